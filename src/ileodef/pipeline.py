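"""End-to-end orchestration: simulate -> score -> quantify -> diversity -> associate.

Produces the joined per-mouse dataset underlying the study's correlation
panels (inflammatory score vs abnormal Paneth cells, reduced/oxidized
cryptdin vs score, diversity and taxa), plus UniFrac/PCoA/PERMANOVA
summaries, written as TSVs with a JSON run manifest.  Reruns with the same
configuration and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, CohortData, generate_cohort
from .defensin import quantify_record
from .diversity import (
    DistanceMatrix,
    OtuTable,
    PhyloTree,
    collapse_taxonomy,
    faith_pd,
    observed_otus,
    pcoa,
    permanova,
    rarefy,
    unifrac_matrix,
)
from .histology import (
    PER_AXIS_CATEGORIES,
    CalibrationBins,
    SectionMeasurements,
    calibrate_lower,
    calibrate_upper,
    count_abnormal_cells,
    score_mouse,
)
from .io import write_cohort_tables
from .stats import pearson

__all__ = [
    "RunConfig",
    "calibrate_cohort",
    "score_cohort",
    "diversity_summary",
    "build_cohort_dataset",
    "default_association_plan",
    "run_associations",
    "run_pipeline",
]

FAMILIES_OF_INTEREST = (
    "Lachnospiraceae",
    "Ruminococcaceae",
    "Bacteroidaceae",
    "Rikenellaceae",
)


def _category_values(sections: Sequence[SectionMeasurements], category: str) -> list[float]:
    return [a.value(category) for s in sections for a in s.axes]


def calibrate_cohort(
    control_sections: Sequence[SectionMeasurements],
    case_sections: Sequence[SectionMeasurements],
) -> dict[str, CalibrationBins]:
    """Calibrate all three per-axis categories from pooled axis values."""
    bins: dict[str, CalibrationBins] = {}
    for cat in ("infiltration", "muscle"):
        bins[cat] = calibrate_upper(
            _category_values(control_sections, cat),
            _category_values(case_sections, cat),
            category=cat,
        )
    bins["villus_distortion"] = calibrate_lower(
        _category_values(control_sections, "villus_distortion"),
        _category_values(case_sections, "villus_distortion"),
    )
    return bins


def score_cohort(
    sections: Sequence[SectionMeasurements],
    control_ids: set[str],
    bins: Mapping[str, CalibrationBins] | None = None,
) -> tuple[pd.DataFrame, dict[str, CalibrationBins]]:
    """Calibrate on the split (unless bins given) and score every mouse."""
    controls = [s for s in sections if s.mouse_id in control_ids]
    cases = [s for s in sections if s.mouse_id not in control_ids]
    if bins is None:
        bins = calibrate_cohort(controls, cases)
    rows = []
    for s in sections:
        sc = score_mouse(s, bins)
        abn = count_abnormal_cells(s)
        rows.append(
            {
                "mouse_id": s.mouse_id,
                **{f"score_{c}": sc.category_scores[c] for c in PER_AXIS_CATEGORIES},
                "score_abscess": sc.abscess_score,
                "score_total": sc.total,
                "abnormal_cells_per_axis": np.nan if abn is None else abn,
            }
        )
    return pd.DataFrame(rows), dict(bins)


@dataclass(frozen=True)
class DiversityResult:
    per_sample: pd.DataFrame
    family_abundance: pd.DataFrame
    genus_abundance: pd.DataFrame
    distance: DistanceMatrix
    pcoa_coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    rarefaction_depth: int


def diversity_summary(
    table: OtuTable,
    tree: PhyloTree,
    taxonomy: Mapping[str, str],
    rarefy_depth: int | str = "auto",
    seed: int = 0,
    rarefy_alpha: bool = True,
) -> DiversityResult:
    """Alpha/beta diversity and taxonomy summaries for one OTU table.

    ``rarefy_depth="auto"`` rarefies to the minimum sample total.  Relative
    abundances are computed on the unrarefied counts (they are
    depth-invariant); alpha diversity on the rarefied table unless
    ``rarefy_alpha`` is off; UniFrac on the rarefied table as well.
    """
    if rarefy_depth == "auto":
        depth = int(table.sample_totals.min())
    else:
        depth = int(rarefy_depth)
    work = rarefy(table, depth, seed) if rarefy_alpha else table

    alpha = pd.DataFrame(
        {
            "sample_id": work.sample_ids,
            "observed_otus": [observed_otus(r) for r in work.counts],
            "faith_pd": [faith_pd(r, tree, work.otu_ids) for r in work.counts],
        }
    ).set_index("sample_id")

    fam = collapse_taxonomy(table, taxonomy, "family")
    gen = collapse_taxonomy(table, taxonomy, "genus")

    dm = unifrac_matrix(work, tree)
    ord_res = pcoa(dm)
    ncol = min(3, ord_res.coordinates.shape[1])
    coords = pd.DataFrame(
        ord_res.coordinates[:, :ncol],
        index=dm.sample_ids,
        columns=[f"PC{i+1}" for i in range(ncol)],
    )
    return DiversityResult(alpha, fam, gen, dm, coords, ord_res.eigenvalues, depth)


def build_cohort_dataset(
    data: CohortData,
    rarefy_depth: int | str = "auto",
    seed: int | None = None,
) -> tuple[pd.DataFrame, DiversityResult, dict[str, CalibrationBins]]:
    """Score, quantify and summarise a generated cohort into one row per mouse."""
    seed = data.config.seed if seed is None else seed
    control_ids = {m.mouse_id for m in data.mice if m.strain == "control"}
    scores, bins = score_cohort([m.section for m in data.mice], control_ids)

    quant = pd.DataFrame(
        [
            {
                "mouse_id": m.mouse_id,
                "ox_ng": (q := quantify_record(m.gel)).ox_ng,
                "r_ng": q.r_ng,
                "total_ng": q.total_ng,
                "negative_r_flag": q.negative_r_flag,
            }
            for m in data.mice
        ]
    )

    div = diversity_summary(
        data.otu_table, data.tree, data.taxonomy, rarefy_depth, seed
    )

    base = pd.DataFrame(
        {
            "mouse_id": [m.mouse_id for m in data.mice],
            "strain": [m.strain for m in data.mice],
            "age_weeks": [m.age_weeks for m in data.mice],
            "latent_severity": [m.latent_severity for m in data.mice],
        }
    )
    df = base.merge(scores, on="mouse_id", how="left").merge(
        quant, on="mouse_id", how="left"
    )
    df = df.merge(
        div.per_sample, left_on="mouse_id", right_index=True, how="left"
    )
    fam = div.family_abundance
    for f in FAMILIES_OF_INTEREST:
        col = fam[f] if f in fam.columns else pd.Series(0.0, index=fam.index)
        df = df.merge(
            col.rename(f"family_{f}"), left_on="mouse_id", right_index=True, how="left"
        )
    if len(df) != len(data.mice):
        raise RuntimeError("join lost or duplicated mice")
    return df, div, bins


def default_association_plan() -> list[dict]:
    """The study's correlation panels, on disease-model mice."""
    plan = [
        {"x": "score_total", "y": "abnormal_cells_per_axis", "subset": "case"},
        {"x": "score_total", "y": "r_ng", "subset": "case"},
        {"x": "score_total", "y": "ox_ng", "subset": "case"},
        {"x": "r_ng", "y": "faith_pd", "subset": "case"},
        {"x": "r_ng", "y": "observed_otus", "subset": "case"},
        {"x": "ox_ng", "y": "faith_pd", "subset": "case"},
        {"x": "ox_ng", "y": "observed_otus", "subset": "case"},
    ]
    for f in FAMILIES_OF_INTEREST:
        plan.append({"x": "r_ng", "y": f"family_{f}", "subset": "case"})
        plan.append({"x": "ox_ng", "y": f"family_{f}", "subset": "case"})
    return plan


def run_associations(df: pd.DataFrame, plan: Sequence[Mapping]) -> pd.DataFrame:
    """Pearson correlations for every planned variable pair."""
    rows = []
    for item in plan:
        sub = df
        if item.get("subset") in ("case", "control"):
            sub = df[df["strain"] == item["subset"]]
        x, y = item["x"], item["y"]
        if x not in df.columns or y not in df.columns:
            raise KeyError(f"association plan references unknown variable {x!r}/{y!r}")
        pair = sub[[x, y]].dropna()
        res = pearson(pair[x].to_numpy(), pair[y].to_numpy())
        rows.append(
            {
                "x": x,
                "y": y,
                "subset": item.get("subset", "all"),
                "n": res.n,
                "r": res.r,
                "t": res.t_statistic,
                "p": res.p_two_sided,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    rarefy_depth: int | str = "auto"
    n_permutations: int = 999
    outdir: str = "results/run"
    plan: tuple = tuple(default_association_plan())


def _hash_config(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    payload = dataclasses.asdict(cfg)
    payload.pop("outdir", None)  # output location is not part of the configuration
    blob = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write per-stage TSVs plus a manifest.

    Returns a bundle with the joined dataset, association table, PERMANOVA
    results and written paths.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        data = generate_cohort(config.cohort)
        paths = write_cohort_tables(data, out / "tables")

        stage = "score+quantify+diversity"
        df, div, bins = build_cohort_dataset(data, config.rarefy_depth)

        stage = "permanova"
        perm_rows = []
        ids = list(div.distance.sample_ids)
        strain = {m.mouse_id: m.strain for m in data.mice}
        age = {m.mouse_id: m.age_weeks for m in data.mice}
        for a in (min(config.cohort.ages), max(config.cohort.ages)):
            keep = [i for i, s in enumerate(ids) if age[ids[i]] == a]
            labels = [strain[ids[i]] for i in keep]
            if len(set(labels)) < 2:
                continue
            sub = DistanceMatrix(
                [ids[i] for i in keep], div.distance.data[np.ix_(keep, keep)]
            )
            f, p = permanova(sub, labels, config.n_permutations, config.cohort.seed + a)
            perm_rows.append({"age_weeks": a, "pseudo_F": f, "p": p, "n": len(keep)})
        perm_df = pd.DataFrame(perm_rows)

        stage = "associate"
        assoc = run_associations(df, config.plan)

        stage = "write"
        df.to_csv(out / "cohort_dataset.tsv", sep="\t", index=False, float_format="%.10g")
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False, float_format="%.10g")
        perm_df.to_csv(out / "permanova.tsv", sep="\t", index=False, float_format="%.10g")
        div.pcoa_coordinates.rename_axis("sample_id").to_csv(
            out / "pcoa_coordinates.tsv", sep="\t", float_format="%.10g"
        )
        div.family_abundance.rename_axis("sample_id").to_csv(
            out / "family_abundance.tsv", sep="\t", float_format="%.10g"
        )
        calib = pd.DataFrame(
            [
                {
                    "category": b.category,
                    "direction": b.direction,
                    "zero_low": b.zero_band[0],
                    "zero_high": b.zero_band[1],
                    "case_extremum": b.case_extremum,
                    "degenerate": b.degenerate,
                }
                for b in bins.values()
            ]
        )
        calib.to_csv(out / "calibration.tsv", sep="\t", index=False, float_format="%.10g")

        written = sorted(
            p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "version": __version__,
            "seed": config.cohort.seed,
            "config_sha256": _hash_config(config),
            "rarefaction_depth": div.rarefaction_depth,
            "n_mice": len(data.mice),
            "files": {
                str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
                for p in written
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        raise
    return {
        "dataset": df,
        "associations": assoc,
        "permanova": perm_df,
        "diversity": div,
        "calibration": bins,
        "manifest": manifest,
        "paths": paths,
    }
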