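"""Curate a small per-measurement LC50 table into a modelling-ready dataset.

Builds a toy CSV of replicate fish LC50 measurements (mg/L and mM),
converts everything to log10 millimolar, aggregates replicates by median,
excludes chemicals whose replicate SD exceeds 1.5 log-mM, assigns
precision weights, and splits train/test.
"""

import tempfile
from pathlib import Path

import spectox as st
import spectox.toxdata as td

CSV = """\
chemical_id,smiles,species,endpoint,exposure,concentration,unit,molar_mass
phenol,c1ccc(O)cc1,fathead_minnow,LC50,static,34,mg/L,94.11
phenol,c1ccc(O)cc1,fathead_minnow,LC50,static,29,mg/L,94.11
phenol,c1ccc(O)cc1,fathead_minnow,LC50,static,41,mg/L,94.11
toluene,Cc1ccccc1,fathead_minnow,LC50,static,0.35,mM,
toluene,Cc1ccccc1,fathead_minnow,LC50,static,0.22,mM,
aniline,Nc1ccccc1,fathead_minnow,LC50,static,1.1,mM,
erratic,CCO,fathead_minnow,LC50,static,0.001,mM,
erratic,CCO,fathead_minnow,LC50,static,900,mM,
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "lc50.csv"
    path.write_text(CSV)
    records = st.parse_toxicity_csv(path)

converted = st.convert_records(records)
aggregated = st.aggregate_replicates(converted)
kept, excluded = st.filter_unreliable(aggregated)          # SD > 1.5 log-mM out
weighted = st.compute_weights(kept)
final = st.split_dataset(weighted, test_fraction=0.2, seed=1)

print(f"records parsed: {len(records)}, unique chemicals: {len(aggregated)}")
print(f"excluded as unreliable (replicate SD > 1.5 log-mM): "
      f"{[c.chemical_id for c in excluded]}")
print(f"pooled replicate SD of kept chemicals: {td.pooled_sd(kept):.3f} log-mM")
print(f"{'chemical':<10}{'log LC50 (mM)':>14}{'SD':>8}{'n':>4}{'weight':>9}{'split':>7}")
for c in final:
    sd = f"{c.sd_exp:.3f}" if c.sd_exp is not None else "-"
    print(f"{c.chemical_id:<10}{c.log_toxicity:>14.3f}{sd:>8}"
          f"{c.n_replicates:>4}{c.weight:>9.3f}{c.split:>7}")

# The median makes each chemical's value robust to a single bad replicate;
# the weight (1 / max(SD, 0.05), rescaled to mean 1) lets precisely measured
# chemicals count more during model training. The "erratic" chemical, whose
# two replicates disagree by ~6 orders of magnitude, is excluded outright.
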