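"""Generate the synthetic multi-site trial dataset used by the analyses.

A diverse panel of 200 accessions x 1,500 SNPs evaluated at 3 sites in
replicated row-column trials with AR1 x AR1 spatial error, four traits
(GY, PH, DF, OL) with study-like genetic/residual covariances and a moderate
genotype-by-site interaction.  Writes genotypes (TSV dosage), the plot-level
trial table and the true effects under results/data/.

Run:  python analysis/01_simulate.py [--seed 1]
"""

import argparse
from pathlib import Path

from safgp import io, sim

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
params = sim.scaled_params(args.seed, n_lines=200, n_markers=1500, n_sites=3,
                           n_reps=2, missing_rate=0.08)
geno = sim.simulate_genotypes(params)
effects = sim.simulate_true_effects(geno, params)
trial = sim.simulate_trial(geno, effects, params)

io.write_dosage_tsv(geno, args.out / "genotypes.tsv")
io.write_trial_csv(trial, args.out / "trial.csv")
effects.g_frame().to_csv(args.out / "true_effects.csv", index_label="accession")

print(f"wrote {geno.n_lines} lines x {geno.n_markers} markers "
      f"({geno.missing_mask.mean():.1%} missing calls)")
print(f"trial table: {len(trial)} plots over {params.n_sites} sites, "
      f"{params.n_reps} replicates, traits {params.traits}")
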