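"""Synthetic cohort generator emulating the study's statistical structure.

Two strains (control vs a spontaneous-ileitis disease model) are sampled at
several ages.  Each disease-model mouse carries a latent severity that rises
with age; severity drives (i) histology measurements through a shared
per-mouse random effect so crypt-villus axes within a mouse are strongly
correlated, (ii) fecal oxidized/reduced cryptdin amounts measured through
gel densitometry, and (iii) microbiota composition: family-level shifts
(Lachnospiraceae and Ruminococcaceae down, Bacteroidaceae and Rikenellaceae
up), loss of within-family evenness and hence of observed richness.
Default means are the emulated study design's reference group summaries; see docs/methods.md
for how the noise scales were chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .defensin import DensitometryRecord
from .diversity import OtuTable, PhyloTree
from .histology import AxisMeasurement, SectionMeasurements

__all__ = [
    "HistologyParams",
    "GelParams",
    "FamilySpec",
    "MicrobiotaParams",
    "CohortConfig",
    "SyntheticMouse",
    "CohortData",
    "generate_cohort",
    "generate_histology",
    "generate_gel",
    "generate_microbiota",
    "build_taxonomy",
    "random_coalescent_newick",
    "derive_lognormal_sigma",
]


@dataclass(frozen=True)
class HistologyParams:
    """Control means/SDs and per-unit-severity effects for the scored categories.

    Disease shifts infiltration and muscle thickness up and the villus/crypt
    ratio down; default effects are 4 control SD at severity 1.  The shared
    per-mouse effect carries ``icc`` of each category's variance and is
    aligned with the disease direction across categories (a sick-looking
    mouse looks sick in every category).
    """

    infiltration_mean: float = 10.0
    infiltration_sd: float = 2.0
    infiltration_effect: float = 8.0
    muscle_mean: float = 30.0  # um
    muscle_sd: float = 4.0
    muscle_effect: float = 16.0
    ratio_mean: float = 3.0  # villus length / crypt depth
    ratio_sd: float = 0.22
    ratio_effect: float = 0.88  # subtracted per unit severity
    crypt_depth_mean: float = 100.0  # um
    crypt_depth_sd: float = 5.0
    abscess_rate_per_severity: float = 2.0  # Poisson rate at severity 1; 0 for controls
    abnormal_cells_control: float = 0.2  # eosinophilic granule-positive cells/axis
    abnormal_cells_case_base: float = 3.54
    abnormal_cells_case_slope: float = 4.76  # 3.54 -> 8.30 across severity 0 -> 1

    def validate(self) -> None:
        for name in ("infiltration_sd", "muscle_sd", "ratio_sd", "crypt_depth_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"histology_params.{name} must be >= 0")
        if self.abscess_rate_per_severity < 0:
            raise ValueError("histology_params.abscess_rate_per_severity must be >= 0")


@dataclass(frozen=True)
class GelParams:
    """Densitometry generator settings.

    ``coupling_r``/``coupling_ox`` are the target Pearson correlations
    between latent severity and the implied ng amounts across the diseased
    cohort; the lognormal noise scale is derived from them, with
    ``assay_cv`` as a severity-independent noise floor.  Coupling 1 with
    ``assay_cv`` 0 means zero noise.
    """

    standard_ng: float = 200.0
    standard_intensity: float = 1000.0
    ox_mean_sev0: float = 6.50  # ng / 500 ug feces
    ox_mean_sev1: float = 11.76
    r_mean_sev0: float = 0.23
    r_mean_sev1: float = 9.82
    coupling_r: float = 0.8
    coupling_ox: float = 0.05
    assay_cv: float = 0.2
    lane_noise_ng_sd: float = 0.5  # additive densitometry noise per lane, ng units
    feces_mass_normalizer: float = 500.0

    def ox_mean(self, severity: float) -> float:
        return self.ox_mean_sev0 + (self.ox_mean_sev1 - self.ox_mean_sev0) * severity

    def r_mean(self, severity: float) -> float:
        return self.r_mean_sev0 + (self.r_mean_sev1 - self.r_mean_sev0) * severity

    def validate(self) -> None:
        if self.standard_ng <= 0 or self.standard_intensity <= 0:
            raise ValueError("gel_params standard lane must be positive")
        for name in ("coupling_r", "coupling_ox"):
            c = getattr(self, name)
            if not 0 < c <= 1:
                raise ValueError(f"gel_params.{name} must be in (0, 1]")
        if self.assay_cv < 0:
            raise ValueError("gel_params.assay_cv must be >= 0")
        if self.lane_noise_ng_sd < 0:
            raise ValueError("gel_params.lane_noise_ng_sd must be >= 0")


@dataclass(frozen=True)
class FamilySpec:
    """One bacterial family: base proportion, proportion at severity 1, genera.

    ``genera`` maps genus name (empty string = unresolved, collapsing to
    '<family>;Other') to its within-family share.
    """

    name: str
    prop_sev0: float
    prop_sev1: float
    lineage_prefix: str  # up to o__ (order)
    genera: Mapping[str, float]


def _default_families() -> tuple[FamilySpec, ...]:
    return (
        FamilySpec(
            "Lachnospiraceae", 0.3437, 0.2486,
            "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales",
            {"": 0.18, "Blautia": 0.42, "Roseburia": 0.40},
        ),
        FamilySpec(
            "Bacteroidaceae", 0.2982, 0.3567,
            "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales",
            {"Bacteroides": 1.0},
        ),
        FamilySpec(
            "Ruminococcaceae", 0.0970, 0.0683,
            "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales",
            {"Anaerotruncus": 0.076, "Ruminococcus": 0.524, "Oscillibacter": 0.40},
        ),
        FamilySpec(
            "Rikenellaceae", 0.0564, 0.0869,
            "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales",
            {"Alistipes": 1.0},
        ),
        FamilySpec(
            "Muribaculaceae", 0.2047, 0.2395,
            "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales",
            {"": 1.0},
        ),
    )


@dataclass(frozen=True)
class MicrobiotaParams:
    """Dirichlet-multinomial community model.

    Per-sample family proportions are a Dirichlet draw around
    log-interpolated (then renormalized) severity-shifted family targets;
    within each family OTU weights follow a geometric series whose ratio
    falls with severity (evenness loss -> observed richness loss); counts
    are one multinomial draw at a lognormal library size.  ``evenness_q0``
    and ``evenness_q1`` were calibrated once so mean observed OTUs at the
    default rarefaction depth match the design's reference 4-wk/20-wk values;
    ``branch_length_mean`` so Faith's PD at severity 0 matches its reference
    value (see docs/methods.md).
    """

    n_otus: int = 250
    families: tuple[FamilySpec, ...] = field(default_factory=_default_families)
    concentration: float = 2000.0
    library_median: float = 20000.0
    library_gsd: float = 1.3  # geometric SD of the lognormal library size
    evenness_q0: float = 0.8850
    evenness_q1: float = 0.8427
    branch_length_mean: float = 0.036

    def validate(self) -> None:
        names = [f.name for f in self.families]
        required = {"Lachnospiraceae", "Ruminococcaceae", "Bacteroidaceae", "Rikenellaceae"}
        if len(self.families) < 4 or not required <= set(names):
            raise ValueError(
                "microbiota_params must configure >= 4 families including "
                + ", ".join(sorted(required))
            )
        for attr in ("prop_sev0", "prop_sev1"):
            s = sum(getattr(f, attr) for f in self.families)
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"family {attr} proportions must sum to 1, got {s}")
        if self.concentration <= 0:
            raise ValueError("microbiota_params.concentration must be > 0")
        if not (0 < self.evenness_q1 <= self.evenness_q0 < 1):
            raise ValueError("evenness ratios must satisfy 0 < q1 <= q0 < 1")


@dataclass(frozen=True)
class CohortConfig:
    n_control_per_age: int = 4
    n_case_per_age: int = 8
    ages: tuple[int, ...] = (4, 10, 20)
    severity_mean_by_age: Mapping[int, float] = field(
        default_factory=lambda: {4: 0.0, 10: 0.5, 20: 1.0}
    )
    severity_sd: float = 0.15
    icc: float = 0.9
    axes_per_mouse: int = 10
    histology_params: HistologyParams = field(default_factory=HistologyParams)
    gel_params: GelParams = field(default_factory=GelParams)
    microbiota_params: MicrobiotaParams = field(default_factory=MicrobiotaParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_control_per_age < 1 or self.n_case_per_age < 1:
            raise ValueError("cohort sizes must be >= 1 per age")
        if list(self.ages) != sorted(set(self.ages)):
            raise ValueError("ages must be strictly increasing")
        missing = [a for a in self.ages if a not in self.severity_mean_by_age]
        if missing:
            raise ValueError(f"severity_mean_by_age missing ages {missing}")
        if self.severity_sd < 0:
            raise ValueError("severity_sd must be >= 0")
        if not 0 <= self.icc < 1:
            raise ValueError("icc must be in [0, 1)")
        if not 1 <= self.axes_per_mouse <= 10:
            raise ValueError("axes_per_mouse must be in 1..10")
        self.histology_params.validate()
        self.gel_params.validate()
        self.microbiota_params.validate()

    @classmethod
    def null(cls, **kwargs) -> "CohortConfig":
        """A zero-effect configuration: strain carries no information."""
        hp = HistologyParams(
            infiltration_effect=0.0, muscle_effect=0.0, ratio_effect=0.0,
            abscess_rate_per_severity=0.0,
            abnormal_cells_case_base=HistologyParams.abnormal_cells_control,
            abnormal_cells_case_slope=0.0,
        )
        base = cls(**kwargs)
        sev0 = {a: 0.0 for a in base.ages}
        gp = replace(base.gel_params, ox_mean_sev1=base.gel_params.ox_mean_sev0,
                     r_mean_sev1=base.gel_params.r_mean_sev0)
        fams = tuple(
            replace(f, prop_sev1=f.prop_sev0) for f in base.microbiota_params.families
        )
        mp = replace(base.microbiota_params, families=fams,
                     evenness_q1=base.microbiota_params.evenness_q0)
        return replace(base, histology_params=hp, gel_params=gp,
                       microbiota_params=mp, severity_mean_by_age=sev0,
                       severity_sd=0.0)


@dataclass(frozen=True)
class SyntheticMouse:
    mouse_id: str
    strain: str  # "control" | "case"
    age_weeks: int
    latent_severity: float
    section: SectionMeasurements
    gel: DensitometryRecord
    microbiota_sample_id: str


@dataclass
class CohortData:
    config: CohortConfig
    mice: list[SyntheticMouse]
    otu_table: OtuTable
    taxonomy: dict[str, str]
    tree_newick: str
    tree: PhyloTree


def derive_lognormal_sigma(
    target_corr: float, mu_values: np.ndarray, assay_cv: float = 0.0
) -> float:
    """Lognormal log-SD giving a target severity<->amount Pearson correlation.

    With multiplicative mean-1 noise m, corr(s, mu(s)*m)^2 =
    Var(mu) / (Var(mu) + E[mu^2] * Var(m)); solve for Var(m) and add the
    assay floor before converting to the log scale.
    """
    mu = np.asarray(mu_values, float)
    a2 = float(np.var(mu))
    if target_corr >= 1.0:
        v = 0.0
    elif a2 == 0.0:
        v = 0.0
    else:
        v = a2 * (1.0 / target_corr**2 - 1.0) / float(np.mean(mu**2))
    v += assay_cv**2
    return math.sqrt(math.log1p(v))


def _lognormal_factor(rng: np.random.Generator, sigma: float) -> float:
    if sigma == 0.0:
        return 1.0
    return math.exp(rng.standard_normal() * sigma - sigma**2 / 2.0)


def generate_histology(
    mouse_id: str,
    mouse_effect: float,
    severity: float,
    params: HistologyParams,
    rng: np.random.Generator,
    *,
    icc: float = 0.9,
    axes_per_mouse: int = 10,
    strain: str = "case",
) -> SectionMeasurements:
    """One mouse's section: correlated axis measurements + abscess count.

    ``mouse_effect`` is the shared standard-normal random effect carrying
    ``icc`` of each category's variance, entering every category in its
    disease direction.
    """
    if axes_per_mouse < 1:
        raise ValueError("axes_per_mouse must be >= 1")
    a, b = math.sqrt(icc), math.sqrt(1.0 - icc)

    def axis_noise() -> np.ndarray:
        return a * mouse_effect + b * rng.standard_normal(axes_per_mouse)

    infil = (
        params.infiltration_mean
        + params.infiltration_effect * severity
        + params.infiltration_sd * axis_noise()
    )
    infil = np.round(np.clip(infil, 0.0, None))
    muscle = (
        params.muscle_mean
        + params.muscle_effect * severity
        + params.muscle_sd * axis_noise()
    )
    ratio = (
        params.ratio_mean
        - params.ratio_effect * severity
        - params.ratio_sd * axis_noise()
    )
    depth = params.crypt_depth_mean + params.crypt_depth_sd * rng.standard_normal(
        axes_per_mouse
    )
    muscle = np.clip(muscle, 1e-6, None)
    ratio = np.clip(ratio, 1e-6, None)
    depth = np.clip(depth, 1e-6, None)

    rate = params.abscess_rate_per_severity * severity
    abscesses = int(rng.poisson(rate)) if rate > 0 else 0

    if strain == "case":
        ab_mean = params.abnormal_cells_case_base + params.abnormal_cells_case_slope * severity
    else:
        ab_mean = params.abnormal_cells_control
    abnormal = rng.poisson(max(ab_mean, 0.0), axes_per_mouse).astype(float)

    axes = [
        AxisMeasurement(
            axis_index=i + 1,
            inflammatory_cells=float(infil[i]),
            villus_length=float(ratio[i] * depth[i]),
            crypt_depth=float(depth[i]),
            muscle_thickness=float(muscle[i]),
        )
        for i in range(axes_per_mouse)
    ]
    return SectionMeasurements(mouse_id, axes, abscesses, list(abnormal))


def generate_gel(
    sample_id: str,
    severity: float,
    params: GelParams,
    rng: np.random.Generator,
    sigma_ox: float | None = None,
    sigma_r: float | None = None,
) -> DensitometryRecord:
    """Densitometry lanes whose implied ox/r ng follow the severity means.

    Amount-level variability is multiplicative lognormal; each lane then
    receives independent additive densitometry noise
    (``params.lane_noise_ng_sd``, in ng units), truncated so intensities
    stay non-negative.  The additive component is what lets the implied
    per-sample reduced amount (Trp- minus Trp+) go negative when the true
    amount is near zero, matching the unclamped per-sample convention.  With
    all noise terms zero, standard-curve quantification round-trips the
    configured ng exactly.
    """
    if sigma_ox is None:
        sigma_ox = math.sqrt(math.log1p(params.assay_cv**2))
    if sigma_r is None:
        sigma_r = math.sqrt(math.log1p(params.assay_cv**2))
    ox_ng = params.ox_mean(severity) * _lognormal_factor(rng, sigma_ox)
    r_ng = params.r_mean(severity) * _lognormal_factor(rng, sigma_r)
    lane_sd = params.lane_noise_ng_sd
    plus_ng = ox_ng
    minus_ng = ox_ng + r_ng
    if lane_sd > 0:
        plus_ng += lane_sd * rng.standard_normal()
        minus_ng += lane_sd * rng.standard_normal()
    slope = params.standard_ng / params.standard_intensity
    return DensitometryRecord(
        sample_id=sample_id,
        standard_ng=params.standard_ng,
        standard_intensity=params.standard_intensity,
        trp_minus_intensity=max(minus_ng, 0.0) / slope,
        trp_plus_intensity=max(plus_ng, 0.0) / slope,
        feces_mass_normalizer=params.feces_mass_normalizer,
    )


def _family_otu_allocation(params: MicrobiotaParams) -> list[int]:
    raw = [f.prop_sev0 * params.n_otus for f in params.families]
    counts = [max(2, int(round(r))) for r in raw]
    while sum(counts) > params.n_otus:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < params.n_otus:
        counts[int(np.argmax(raw))] += 1
    return counts


def build_taxonomy(params: MicrobiotaParams) -> tuple[list[str], dict[str, str], list[int]]:
    """OTU ids, OTU -> lineage string, and per-OTU family index."""
    otu_ids: list[str] = []
    taxonomy: dict[str, str] = {}
    fam_index: list[int] = []
    counts = _family_otu_allocation(params)
    k = 0
    for fi, (fam, n_f) in enumerate(zip(params.families, counts)):
        genera = list(fam.genera.items())
        # deterministic assignment of OTUs to genera, proportional to shares
        alloc = [max(1, int(round(share * n_f))) for _, share in genera]
        while sum(alloc) > n_f:
            alloc[int(np.argmax(alloc))] -= 1
        while sum(alloc) < n_f:
            alloc[int(np.argmax(alloc))] += 1
        gnames: list[str] = []
        for (gname, _), a in zip(genera, alloc):
            gnames.extend([gname] * a)
        for j in range(n_f):
            oid = f"OTU{k:04d}"
            g = gnames[j]
            taxonomy[oid] = f"{fam.lineage_prefix};f__{fam.name};g__{g}"
            otu_ids.append(oid)
            fam_index.append(fi)
            k += 1
    return otu_ids, taxonomy, fam_index


def _family_proportions(params: MicrobiotaParams, severity: float) -> np.ndarray:
    """Log-interpolated family proportions, renormalized onto the simplex."""
    p0 = np.array([f.prop_sev0 for f in params.families])
    p1 = np.array([f.prop_sev1 for f in params.families])
    logp = (1.0 - severity) * np.log(p0) + severity * np.log(p1)
    p = np.exp(logp)
    return p / p.sum()


def _within_family_weights(n: int, q: float) -> np.ndarray:
    w = q ** np.arange(n)
    return w / w.sum()


def otu_proportions(
    params: MicrobiotaParams,
    severity: float,
    fam_index: Sequence[int],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-OTU expected proportions for one sample (Dirichlet if rng given)."""
    fam_p = _family_proportions(params, severity)
    if rng is not None and np.isfinite(params.concentration):
        fam_p = rng.dirichlet(params.concentration * fam_p)
    q = params.evenness_q0 + (params.evenness_q1 - params.evenness_q0) * min(
        max(severity, 0.0), 1.0
    )
    fam_index = np.asarray(fam_index)
    props = np.empty(fam_index.size)
    for fi in range(len(params.families)):
        mask = fam_index == fi
        props[mask] = fam_p[fi] * _within_family_weights(int(mask.sum()), q)
    return props


def generate_microbiota(
    severity: float,
    params: MicrobiotaParams,
    rng: np.random.Generator,
    fam_index: Sequence[int],
) -> np.ndarray:
    """Counts for one sample: Dirichlet family draw -> OTU split -> multinomial."""
    props = otu_proportions(params, severity, fam_index, rng)
    lib = int(
        round(params.library_median * math.exp(rng.standard_normal() * math.log(params.library_gsd)))
    )
    lib = max(lib, 1)
    return rng.multinomial(lib, props)


def random_coalescent_newick(
    otu_ids: Sequence[str], rng: np.random.Generator, branch_length_mean: float
) -> str:
    """Random binary topology with exponential branch lengths, as Newick."""
    nodes = [f"{oid}" for oid in otu_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b1, b2 = rng.exponential(branch_length_mean, 2)
        merged = f"({nodes[i]}:{b1:.6f},{nodes[j]}:{b2:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ":0.0;"


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate the full joined dataset: histology, gels, microbiota, tree.

    Deterministic given ``config.seed``: all randomness flows from one root
    SeedSequence via named substreams per stage.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_sev, rng_hist, rng_gel, rng_micro, rng_tree = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    # --- latent severities -------------------------------------------------
    plan: list[tuple[str, str, int, float]] = []
    for age in config.ages:
        for i in range(config.n_control_per_age):
            plan.append((f"ctrl_w{age}_{i:02d}", "control", age, 0.0))
        mu = config.severity_mean_by_age[age]
        for i in range(config.n_case_per_age):
            s = max(0.0, mu + config.severity_sd * rng_sev.standard_normal())
            plan.append((f"case_w{age}_{i:02d}", "case", age, s))

    case_sev = np.array([s for _, strain, _, s in plan if strain == "case"])
    gp = config.gel_params
    sigma_ox = derive_lognormal_sigma(
        gp.coupling_ox, np.array([gp.ox_mean(s) for s in case_sev]), gp.assay_cv
    )
    sigma_r = derive_lognormal_sigma(
        gp.coupling_r, np.array([gp.r_mean(s) for s in case_sev]), gp.assay_cv
    )

    # --- microbiota scaffolding (once per cohort) --------------------------
    mp = config.microbiota_params
    otu_ids, taxonomy, fam_index = build_taxonomy(mp)
    newick = random_coalescent_newick(otu_ids, rng_tree, mp.branch_length_mean)
    tree = PhyloTree.from_newick(newick)

    mice: list[SyntheticMouse] = []
    count_rows: list[np.ndarray] = []
    for mouse_id, strain, age, sev in plan:
        section = generate_histology(
            mouse_id,
            float(rng_hist.standard_normal()),
            sev,
            config.histology_params,
            rng_hist,
            icc=config.icc,
            axes_per_mouse=config.axes_per_mouse,
            strain=strain,
        )
        gel = generate_gel(mouse_id, sev, gp, rng_gel, sigma_ox, sigma_r)
        count_rows.append(generate_microbiota(sev, mp, rng_micro, fam_index))
        mice.append(SyntheticMouse(mouse_id, strain, age, sev, section, gel, mouse_id))

    table = OtuTable([m.mouse_id for m in mice], otu_ids, np.vstack(count_rows))
    return CohortData(config, mice, table, taxonomy, newick, tree)
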