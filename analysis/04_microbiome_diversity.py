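#!/usr/bin/env python
"""Microbiome diversity and composition of the simulated cohort.

Rarefies to the minimum library size, computes observed OTUs and Faith's PD,
collapses taxonomy to family/genus relative abundances, builds the
unweighted-UniFrac distance matrix, ordinates it with PCoA, and tests
strain separation with PERMANOVA at the youngest and oldest ages.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ileodef.diversity import DistanceMatrix, permanova
from ileodef.io import read_otu_table, read_taxonomy, read_tree
from ileodef.pipeline import diversity_summary

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "diversity"
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = read_otu_table(COHORT / "otu_table.tsv")
    tree = read_tree(COHORT / "tree.nwk")
    taxonomy = read_taxonomy(COHORT / "taxonomy.tsv")
    meta = pd.read_csv(COHORT / "cohort.tsv", sep="\t").set_index("mouse_id")

    res = diversity_summary(table, tree, taxonomy, "auto", SEED)
    print(f"rarefied every sample to {res.rarefaction_depth} reads")

    alpha = res.per_sample.join(meta)
    alpha.rename_axis("sample_id").to_csv(OUT / "alpha_diversity.tsv", sep="\t",
                                          float_format="%.10g")
    print("\nalpha diversity by strain and age:")
    print(alpha.groupby(["strain", "age_weeks"])[["observed_otus", "faith_pd"]]
          .mean().round(2))

    fam = res.family_abundance.join(meta)
    fam.rename_axis("sample_id").to_csv(OUT / "family_abundance.tsv", sep="\t",
                                        float_format="%.10g")
    focal = ["Lachnospiraceae", "Ruminococcaceae", "Bacteroidaceae", "Rikenellaceae"]
    case = fam[fam.strain == "case"]
    print("\ndisease-model family relative abundance (%) by age:")
    print((100 * case.groupby("age_weeks")[focal].mean()).round(2))

    res.pcoa_coordinates.rename_axis("sample_id").to_csv(
        OUT / "pcoa_coordinates.tsv", sep="\t", float_format="%.10g")
    pd.DataFrame(res.distance.data, index=res.distance.sample_ids,
                 columns=res.distance.sample_ids).rename_axis("sample_id").to_csv(
        OUT / "unifrac_distance.tsv", sep="\t", float_format="%.10g")

    print("\nPERMANOVA, control vs disease model (unweighted UniFrac):")
    ids = res.distance.sample_ids
    for age in (meta.age_weeks.min(), meta.age_weeks.max()):
        keep = [i for i, s in enumerate(ids) if meta.loc[s, "age_weeks"] == age]
        labels = [meta.loc[ids[i], "strain"] for i in keep]
        sub = DistanceMatrix([ids[i] for i in keep],
                             res.distance.data[np.ix_(keep, keep)])
        f, p = permanova(sub, labels, n_perm=999, seed=SEED + int(age))
        print(f"  {age} wk: pseudo-F = {f:.2f}, p = {p:.3f} (n = {len(keep)})")


if __name__ == "__main__":
    main()
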