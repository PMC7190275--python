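"""Reusable study-level experiments built on the generator + pipeline.

These are the computations behind the headline properties of the analysis:
the control-strain calibration coverage (fraction of control mice whose
total inflammatory score is exactly 0 under in-sample calibration) and the
qualitative association pattern between reduced/oxidized cryptdin, the
inflammatory score, alpha diversity and the shifted bacterial families.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .cohort import CohortConfig, generate_cohort
from .pipeline import build_cohort_dataset, default_association_plan, run_associations, score_cohort

__all__ = [
    "coverage_config",
    "calibration_coverage",
    "SIGN_PATTERN_CLAUSES",
    "sign_pattern_check",
]


def coverage_config(seed: int) -> CohortConfig:
    """Calibration-coverage design: one age, 20 control + 20 diseased mice,
    10 axes, shared-effect ICC 0.9, diseased means 4 control SD into the
    disease direction (the generator defaults), controls abscess-free."""
    return CohortConfig(
        n_control_per_age=20,
        n_case_per_age=20,
        ages=(20,),
        severity_mean_by_age={20: 1.0},
        severity_sd=0.0,
        seed=seed,
    )


def calibration_coverage(seeds: Sequence[int]) -> np.ndarray:
    """Per-seed fraction of control mice scoring exactly 0 in-sample."""
    fractions = []
    for seed in seeds:
        data = generate_cohort(coverage_config(seed))
        control_ids = {m.mouse_id for m in data.mice if m.strain == "control"}
        scores, _ = score_cohort([m.section for m in data.mice], control_ids)
        ctrl = scores[scores.mouse_id.isin(control_ids)]
        fractions.append(float((ctrl.score_total == 0.0).mean()))
    return np.asarray(fractions)


# (x, y, expected sign) with sign 0 meaning "must NOT be significant";
# mirrors the study's correlation panels on disease-model mice.
SIGN_PATTERN_CLAUSES: tuple[tuple[str, str, int], ...] = (
    ("score_total", "r_ng", 1),
    ("r_ng", "family_Bacteroidaceae", 1),
    ("r_ng", "faith_pd", -1),
    ("r_ng", "observed_otus", -1),
    ("r_ng", "family_Lachnospiraceae", -1),
    ("r_ng", "family_Ruminococcaceae", -1),
    ("ox_ng", "faith_pd", 0),
    ("ox_ng", "observed_otus", 0),
)


def sign_pattern_check(
    seeds: Sequence[int], alpha: float = 0.05, config: CohortConfig | None = None
) -> dict[tuple[str, str, int], int]:
    """Count, per association clause, the seeds where it holds.

    A signed clause holds when the Pearson correlation has the expected sign
    and p < alpha; a sign-0 clause holds when p >= alpha.
    """
    base = config or CohortConfig()
    counts = {c: 0 for c in SIGN_PATTERN_CLAUSES}
    for seed in seeds:
        data = generate_cohort(dataclasses.replace(base, seed=seed))
        df, _, _ = build_cohort_dataset(data)
        assoc = run_associations(df, default_association_plan()).set_index(["x", "y"])
        for x, y, sgn in SIGN_PATTERN_CLAUSES:
            key = (x, y) if (x, y) in assoc.index else (y, x)
            row = assoc.loc[key]
            if sgn == 0:
                counts[(x, y, sgn)] += int(row.p >= alpha)
            else:
                counts[(x, y, sgn)] += int(np.sign(row.r) == sgn and row.p < alpha)
    return counts
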