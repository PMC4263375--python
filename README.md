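# meiomotion

Quantitative analysis of meiotic chromosome movement in mouse spermatocytes,
paired with a ground-truth simulator that makes every measurement verifiable.

During meiotic prophase I, telomeres are tethered to the nuclear envelope (NE)
by the LINC complex (SUN1–KASH5) and dragged along microtubule (MT) cables,
producing two superimposed motions — rapid per-telomere movement on the NE and
a unidirectional rotation of the whole nucleus — while actin drives an
oscillation of nuclear shape. These dynamics are stage-specific: fast in
leptotene/zygotene and pachytene (~0.12–0.13 µm/s per-interval 3D speed at 7 s
sampling), transiently suppressed for bouquet-clustered telomeres, and reduced
in diplotene (~0.083 µm/s), where desynapsed homolog ends stay coordinated
(short-arm pairs < 1 µm apart on pericentromeric heterochromatin, long-arm
pairs within 4.5 µm via the chiasma).

`meiomotion` implements both sides of such a study:

- **Simulator** (`presets`, `simulate`, `render`): per-stage motion models
  (persistent great-circle walks + rigid rotation on a deforming envelope,
  pair tethers, bouquet cap, NE detachment), rendered as two-channel 4D stacks
  (Gaussian PSF, Poisson + read noise) and 2D chromosome spreads with MT
  cables, with full ground-truth export.
- **Measurement pipeline** (`detect`, `tracking`, `motion`, `shape`,
  `spread_analysis`, `pipeline`): anisotropic LoG spot detection with
  sub-voxel localization, nucleus masks and signed-distance boundaries, gated
  Hungarian particle linking, per-interval 3D velocimetry, Kabsch rotation
  estimation with a unidirectionality index, homolog pair-distance series,
  bouquet clustering metrics, the XOR nuclear-shape oscillation statistic
  `area(XOR(A_T, A_{T+1}))/area(A_T)`, focus counting, internal-telomere
  classification and telomere/cable colocalization, plus the two-tailed Welch
  t-test used for group comparisons.

## Worked example

```sh
python examples/02_stage_velocities.py
```

```
leptozygotene  measured 0.111 µm/s (published 0.12) from 100 intervals
pachytene      measured 0.134 µm/s (published 0.13) from 100 intervals
diplotene      measured 0.093 µm/s (published 0.083) from 100 intervals
```

Each line is the pooled mean of per-interval 3D chord speeds from 5 telomeres
traced for 10 continuous 7-s intervals in each of two rendered synthetic
cells — the published tracing protocol run end to end (simulate → render →
detect → link → select → measure). With the full five cells the means land
within a few percent of the published stage values. The other examples cover
rendering (`01`), nuclear-rotation estimation (`03`, recovering the rotation
axis to ~2° from tracked heterochromatin), diplotene pair coordination (`04`),
the drug-condition shape-oscillation ordering (`05`), and spread
counting/colocalization (`06`).

A thin CLI mirrors the main entry points
(`meiomotion simulate|render-spread|detect|track|stats|shape|spread|run`);
`meiomotion run --config cfg.yaml` executes a full configured experiment and
writes a checksum manifest next to its outputs.

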