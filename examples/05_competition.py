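"""Full pooled-competition analysis: detect an adhesion-deficient strain.

Simulates three experiments x three technical replicates of washed and
unwashed enteroid wells for a nine-strain mixture in which one strain
(dcmbA) carries a -2.5 percentage-point adhesion deficit, runs every
sample through the demultiplexing pipeline, and tests washed vs unwashed
delta% per strain (two-tailed Welch t-test, unadjusted).
"""

from barcodeq import competition_table, delta_percent, demux_sample, parse_template
from barcodeq import reference as ref
from barcodeq.simulate import SimConfig, gen_competition_experiment

template = parse_template(ref.BARCODE_TEMPLATE_OLIGO)
whitelist = ref.strain_whitelist()

cfg = SimConfig(seed=0, read_depth=10_000, per_base_error_rate=0.001)
sim = gen_competition_experiment(cfg, whitelist, template)
print(f"simulated {len(sim.samples)} samples "
      f"({cfg.n_experiments} experiments x [1 T0 + {cfg.n_technical} washed "
      f"+ {cfg.n_technical} unwashed])")

t0 = {}
washed = {s: [] for s in sim.strains}
unwashed = {s: [] for s in sim.strains}
tf = []
for s in sim.samples:
    counts, _ = demux_sample(s.pairs, template, whitelist, sample_id=s.sample_id)
    (t0.__setitem__(s.experiment, counts) if s.condition == "t0" else tf.append((s, counts)))
for meta, counts in tf:
    d = delta_percent(t0[meta.experiment], counts).set_index("strain")["delta_percent"]
    bucket = washed if meta.condition == "washed" else unwashed
    for strain in sim.strains:
        bucket[strain].append(d[strain])

table = competition_table(washed, unwashed)
print(table.round(4).to_string(index=False))
print(
    "\n'reduced_adhesion' flags strains whose washed delta% is significantly "
    "below the unwashed\ncontrol (p < 0.05). Closure pushes small positive "
    "spillover onto the other strains, which\nis expected and not flagged."
)
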