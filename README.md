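# udmc — Ultra-dense Motion Capture for 4D surface scans

`udmc` reveals **dense inter-frame correspondence** in 4D surface-scan
sequences of the breast: which material point in frame *i* becomes which
point in frame *i+1*.  4D scanners deliver a triangle mesh per frame at up
to 120 fps, but each frame is reconstructed independently — vertex counts
and connectivity differ, so the deformation of any particular skin point is
not directly observable.  Optical MoCap tracks that correspondence exactly,
but only at the ~30 marker positions.  `udmc` combines the two streams:

1. **TPS motion model** — for each consecutive frame pair, a 3D thin-plate
   spline `f(x) = a₀ + aᵀx + Σₖ ωₖ φ(‖x − cₖ‖)` with kernel
   `φ(r) = r² log r` is solved on the landmark pairs
   `cₖ⁽ⁱ⁾ → cₖ⁽ⁱ⁺¹⁾` and transports every vertex of the cropped breast
   mesh to an estimate of its next-frame position;
2. **post-alignment** — each transported vertex is replaced by its nearest
   point on the actually scanned next-frame surface (closest point on the
   triangulated surface), restoring the fine-scale geometry the sparse
   model cannot know;
3. **continuous correspondence field** — an arbitrary query point is mapped
   by a local TPS solved on its M (default 20) nearest frame-*i* vertices
   and their aligned partners.

Chaining the per-pair fields tracks **virtual landmarks** — arbitrary,
unmarked surface points — through the whole sequence, and the trajectory
length of evenly sampled points gives a **deformation-intensity** map of
the breast surface.  The package also contains the supporting pipeline:
spatio-temporal calibration of the MoCap stream to the scanner (similarity
transform `x_scan = s·R_fine·R_axis·x_mocap + T` plus a grid-searched clock
offset `t_scan = t_mocap + δ`), automatic breast cropping from six contour
landmarks, quadric-error-metric decimation, and a synthetic 4D phantom with
exact ground-truth correspondence used by the test suite.

It is aimed at researchers in breast biomechanics, anthropometry and
ergonomic garment design who need full-surface deformation measurements
rather than a handful of marker tracks.

## Worked example

Generate a bouncing-breast phantom (11 frames at 10 fps, ~3000 vertices per
frame, independently remeshed; 30 exact landmarks), crop, register, and
evaluate tracking accuracy:

```python
import numpy as np
from udmc import (PhantomSpec, generate_phantom_sequence, crop_breast,
                  MeshSequence, register_sequence, eval_control_error,
                  eval_loo_error, deformation_intensity)

spec = PhantomSpec(motion="bounce_swing", remesh=True, seed=0)
data = generate_phantom_sequence(spec)
cropped = MeshSequence(
    [crop_breast(m, lf) for m, lf in zip(data.sequence.frames,
                                         data.landmark_frames)],
    fps=spec.fps)
fields = register_sequence(cropped, data.landmark_frames)

control = eval_control_error(fields, data.landmarks)
loo = eval_loo_error(cropped, data.landmark_frames, data.landmarks)
imap = deformation_intensity(cropped, fields, n_samples=100)

print(f"control-landmark error: {control.mean * 0.1:.3f} cm (SD {control.sd * 0.1:.3f})")
print(f"leave-one-out error:    {loo.mean * 0.1:.3f} cm (SD {loo.sd * 0.1:.3f})")
print(f"deformation intensity:  {imap.intensity.min():.1f} - {imap.intensity.max():.1f} mm")
```

```
control-landmark error: 0.047 cm (SD 0.057)
leave-one-out error:    0.051 cm (SD 0.057)
deformation intensity:  0.8 - 168.4 mm
```

The *control* error tracks seeds placed at the frame-1 landmark positions
and compares against the exact landmark tracks — it measures how well the
field follows its own guidance.  The *leave-one-out* error excludes each
landmark from the motion model in turn and tracks it as a held-out point —
an estimate of accuracy at arbitrary unmarked points.  The intensity range
shows near-static tissue at the breast boundary versus ~17 cm of
accumulated travel near the apex over the 1-second sequence.

The same pipeline is available from the shell:

```sh
udmc phantom --spec spec.toml --out data/
udmc crop --scan data/ --landmarks data/ground_truth.csv --out cropped/
udmc register --scan cropped/ --landmarks data/ground_truth.csv --out fields/
udmc eval --mode loo --scan cropped/ --landmarks data/ground_truth.csv --out report.csv
```

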