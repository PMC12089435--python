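# dmlc2d — two-dimensional dynamic MLC leaf-motion calculation

In intensity-modulated radiotherapy (IMRT) a multileaf collimator (MLC)
sweeps an open aperture across the field ("sliding window") to deliver a
planned 2-D intensity pattern, the *optimal fluence map*. Commercial
machines move only the leaves, along x; the leaf bank itself is fixed, so
the deliverable (*actual*) fluence is quantized in y at the 5 mm leaf
width and systematically over-covers the target's superior and inferior
borders. The **2-D dynamic MLC (2DDMLC)** technique adds a second degree
of freedom: a rigid translation of the whole bank along y, re-optimized
for each sector of the sweep, by at most half a leaf width (±2.5 mm for
5 mm leaves) in 0.25 mm steps. Sub-leaf alignment of the bank with the
target border removes most of the out-of-field irradiation without
touching the in-field fluence.

`dmlc2d` is a leaf-motion calculator (LMC) for this technique, aimed at
medical-physics researchers. It provides:

- **Sequencer** — converts per-leaf-pair fluence profiles Φ(x) (in
  monitor units, MU) into leaf arrival times on the MU clock. With
  leading (right) and trailing (left) leaf arrivals R, L at the beamlet
  centres, minimum per-beamlet step τ = dx·(dose rate)/(60·v_max), and
  ΔΦ the beamlet-to-beamlet change:

  R(i+1) = R(i) + τ + max(0, −ΔΦ),  L(i) = R(i) + Φ(i)

  so the delivered exposure L − R reproduces Φ *exactly* at every
  beamlet centre while both leaves sweep monotonically within the speed
  limit.
- **Bank-offset optimizer** — partitions the map into 8 x-sectors and,
  per sector, exhaustively scores the 21 candidate offsets by actually
  sequencing the sector and measuring the normalized mean absolute
  difference between deliverable and optimal fluence. Offset 0 is always
  a candidate, so the plan can never be worse than conventional delivery.
- **Delivery simulator** — analytic reconstruction of the actual fluence
  from a control-point sequence (closed-form exposure per cell), plus a
  brute-force time-stepped oracle used to cross-check it.
- **Metrics** — conformity index CI = (actual irradiated area)/(planned
  irradiated area) at a 10 %-of-maximum threshold, mean intensity, mean
  absolute difference (%), out-of-field area, and paired t statistics
  over case suites.
- **Fixture generator** — seeded synthetic optimal fluence maps (small
  20–30 mm and large 60–80 mm target regimes with random sub-leaf edge
  phases), since clinical TPS exports are not redistributable.

## Worked example

A uniform rectangle spanning y ∈ [2.5, 27.5) mm sits half a leaf width
off the 5 mm leaf boundaries — the worst case for a conventional MLC:

```python
import json
from dmlc2d import MLCGeometry, MachineConfig, compare_techniques
from dmlc2d.fixtures import worked_rectangle

report = compare_techniques(
    worked_rectangle(), MLCGeometry.millennium120(), MachineConfig()
)
print(json.dumps(report.to_dict(), indent=2))
```

prints (abridged):

```json
{
  "ci_conventional": 1.2,
  "ci_2ddmlc": 1.0,
  "mean_intensity_conventional": 500.0,
  "mean_intensity_2ddmlc": 500.0,
  "mad_pct_conventional": 16.666666666666668,
  "mad_pct_2ddmlc": 6.25e-15,
  "oof_area_conventional": 200.0,
  "oof_area_2ddmlc": 0.0,
  "oof_reduction_pct": 100.0,
  "sector_offsets": [2.5, 2.5, 2.5, 2.5, 2.5, 2.5, 2.5, 2.5]
}
```

The conventional technique must open six 5 mm pairs to cover a 25 mm
target (CI = 30/25 = 1.2, two 2.5 mm over-coverage bands totalling
200 mm²); the optimizer selects a +2.5 mm bank offset in every sector,
after which five pairs cover the target exactly: CI = 1, zero
out-of-field area, and the delivered map matches the plan to machine
precision. The mean intensity (here the 500 MU scaling maximum, uniform
map) is identical for both techniques.

The same pipeline is scriptable from a shell:

```bash
dmlc2d generate --regime small --n 50 --seed 1 --out maps
dmlc2d compare --manifest maps/manifest.json --out results
dmlc2d sequence maps/fluence_000.txt --technique 2ddmlc --out seq
dmlc2d reconstruct seq/sequence.tsv --out actual
```

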