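"""Marker QC and genomic relationship matrix.

Filters markers (missing < 50%, MAF > 0.01), imputes the survivors with the
marker-mean filler and builds the VanRaden method-1 GRM, lightly conditioned
for REML.  Writes the filtered panel and GRM under results/data/.

Run:  python analysis/02_qc_grm.py
"""

import argparse
from pathlib import Path

import numpy as np

from safgp import io, qc

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
args = parser.parse_args()

geno = io.read_dosage_tsv(args.data / "genotypes.tsv")
kept = qc.filter_markers(geno, max_missing=0.5, min_maf=0.01)
imputed = qc.impute_missing(kept, "mean_dosage")
grm = qc.condition_grm(qc.vanraden_grm(imputed))

io.write_dosage_tsv(imputed, args.data / "genotypes_filtered.tsv")
io.write_grm_tsv(grm, args.data / "grm.tsv")

diag = np.diag(grm.values)
print(f"kept {kept.n_markers}/{geno.n_markers} markers after QC")
print(f"GRM: {grm.n} accessions, mean diagonal {diag.mean():.3f} "
      f"(expect ~1 under Hardy-Weinberg)")
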