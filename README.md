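# vbb — virtual bone bank toolkit

Structural bone allografts (cadaveric bone segments used to reconstruct
skeletal defects after tumor resection) work best when the donor bone
closely matches the host's anatomy: a poor match destabilizes the joint and
accelerates cartilage degeneration. `vbb` implements the virtual bone bank
workflow for selecting the best donor from a CT-scanned bank of bones:

1. **Segmentation & reconstruction** — threshold a CT-like volume into a
   bone mask (cortical bone is high-intensity), keep the largest connected
   component, and extract a triangle mesh in mm coordinates with marching
   cubes.
2. **Mirror model** — tumors erode the host's anatomy, so the intact
   contralateral bone is reflected across the sagittal plane to stand in for
   the resected side's geometry.
3. **ABC size screening** — six operator-placed landmarks define three
   distances on the distal femur: A = ‖ME − LE‖ (transepicondylar width),
   B = ‖MA − MP‖ (medial condyle AP depth), C = ‖LA − LP‖ (lateral condyle
   AP depth). Donors are ranked by the Euclidean distance between donor and
   host (A, B, C) vectors and the closest k proceed.
4. **Rigid registration** — each screened donor is aligned to the host
   mirror model: closed-form landmark (Kabsch) initialization, refined by
   trimmed iterative closest point with exact point-to-surface
   correspondences. Trimming discards the worst fraction of correspondences
   each iteration, absorbing the host's missing (tumor-eroded) regions.
   Scaling is never estimated and reflections are impossible by
   construction, so true sizes and chirality are always compared.
5. **Match scoring** — the goodness-of-match is the mean of per-point
   distances from the host surface cloud to the registered donor surface
   (RMS, one-sided Hausdorff max and 95th percentile are also reported),
   plus a colorimetric PLY export that paints local mismatch onto the
   surface.

No clinical data ships with the package: a synthetic-anatomy module
generates parametric distal-femur-like bones with ground-truth landmarks,
controllable A/B/C dimensions, left/right chirality, surface noise,
tumor-like defects, and rasterized CT-like volumes (0.5 mm voxels by
default), so the entire pipeline is testable end to end.

## Worked example

```sh
# 1. simulate a 20-donor right-side bank
vbb simulate --n 20 --seed 42 --out bank/ --side right

# 2. screen it against a host with A=81, B=59, C=63 mm
vbb screen bank/bank.csv --host-abc 81,59,63 --k 3
```

which prints (ascending ABC distance, ties broken by donor id):

```
donor_0004  d=1.805 mm  (dA=+0.87 dB=-1.58 dC=+0.11)
donor_0014  d=2.195 mm  (dA=-0.73 dB=+1.87 dC=+0.89)
donor_0000  d=2.471 mm  (dA=+0.22 dB=-2.12 dC=+1.25)
```

`d` is the Euclidean distance in (A, B, C) space in mm; the per-measure
deltas show where each candidate is larger (+) or smaller (−) than the
host. Full surface matching of the screened candidates then runs with

```sh
vbb match host_mirror.stl --bank bank/bank.csv --host-landmarks host.json \
    --k 3 --out report.json --color-dir colored/
```

which reports, per candidate, the mean/RMS/max/p95 surface distances and
writes distance-colored PLY surfaces; `report.json` ranks candidates by
mean distance. The one-command workflow (`vbb run --config case.toml`)
chains segmentation, mirroring, measurement, screening, registration and
scoring, and writes a reproducible manifest. The same functionality is
available as a library (`import vbb`).

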