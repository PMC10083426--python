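"""Genomic variance components: heritability and genetic correlations.

Univariate GBLUP per (site, trait) for narrow-sense h2; bivariate fits at the
first site for the GY-PH and GY-OL genetic correlations; the g x E model for
grain yield across sites.  Writes a components table under results/.

Run:  python analysis/04_genetic_parameters.py
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from safgp import io, reml

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

blues = pd.read_csv(args.data / "blues.csv")
grm = io.read_grm_tsv(args.data / "grm.tsv")
sites = list(blues["site"].unique())
traits = list(blues["trait"].unique())

rows = []
for site in sites:
    for trait in traits:
        sub = blues[(blues["site"] == site) & (blues["trait"] == trait)]
        comps, _ = reml.fit_univariate(sub, grm)
        rows.append({"site": site, "trait": trait, "sigma2_A": comps.sigma2_A,
                     "sigma2_e": comps.sigma2_e, "h2": comps.h2})
table = pd.DataFrame(rows)
table.to_csv(args.out / "variance_components.csv", index=False)
print(table.pivot(index="trait", columns="site", values="h2").round(2).to_string())

first = sites[0]
corr_out = {}
for pair in (("GY", "PH"), ("GY", "OL")):
    sub = blues[(blues["site"] == first) & (blues["trait"].isin(pair))]
    comps, _, corrs = reml.fit_multitrait(sub, grm, traits=list(pair))
    corr_out["_".join(pair)] = {"r_A": corrs[0].r_A, "r_P": corrs[0].r_P}
    print(f"{first} {pair[0]}-{pair[1]}: r_A={corrs[0].r_A:+.2f} r_P={corrs[0].r_P:+.2f}")

gxe, _ = reml.fit_gxe(blues, grm, trait="GY")
print(f"g x E (GY, {len(sites)} sites): sigma2_A={gxe['sigma2_A']:.3f} "
      f"sigma2_gxe={gxe['sigma2_gxe']:.3f} sigma2_e={gxe['sigma2_e']:.3f}")
(args.out / "correlations.json").write_text(json.dumps(
    {"pairs": corr_out, "gxe_GY": {k: float(v) for k, v in gxe.items()}}, indent=1))
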