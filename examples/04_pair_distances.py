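"""Diplotene homolog pair coordination.

After desynapsis, homolog telomere pairs stay connected: short-arm ends ride
pericentromeric heterochromatin (tight, < 1 µm) while long-arm ends are held
only by the chiasma (loose, < 4.5 µm). The experiment simulates one cell for
3.5 minutes, runs the full pipeline and reports the maximum 3D separation
per arm class.
"""
import meiomotion as mm

res = mm.pair_distance_experiment(seed=1)
print(f"short-arm pairs (n={res.n_short_pairs}): max separation "
      f"{res.max_short_um:.2f} µm (published bound < 1 µm)")
print(f"long-arm pairs  (n={res.n_long_pairs}): max separation "
      f"{res.max_long_um:.2f} µm (published bound <= 4.5 µm)")
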