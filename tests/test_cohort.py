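"""Synthetic cohort generator: determinism, couplings, null soundness."""

import dataclasses

import numpy as np
import pytest

from ileodef.cohort import (
    CohortConfig,
    GelParams,
    HistologyParams,
    MicrobiotaParams,
    build_taxonomy,
    generate_cohort,
    generate_histology,
    otu_proportions,
)
from ileodef.defensin import quantify_record
from ileodef.stats import mann_whitney_u

SMALL = CohortConfig(n_control_per_age=3, n_case_per_age=3, seed=7)


def _hash_cohort(data) -> str:
    import hashlib
    import io

    from ileodef.io import write_cohort_tables

    h = hashlib.sha256()
    h.update(data.tree_newick.encode())
    h.update(data.otu_table.counts.tobytes())
    for m in data.mice:
        h.update(repr((m.mouse_id, m.latent_severity, m.gel, m.section)).encode())
    return h.hexdigest()


class TestDeterminism:
    def test_same_seed_identical_output(self):
        assert _hash_cohort(generate_cohort(SMALL)) == _hash_cohort(generate_cohort(SMALL))

    def test_different_seed_differs(self):
        other = dataclasses.replace(SMALL, seed=8)
        assert _hash_cohort(generate_cohort(SMALL)) != _hash_cohort(generate_cohort(other))


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            ({"icc": 1.0}, "icc"),
            ({"severity_sd": -1.0}, "severity_sd"),
            ({"ages": (10, 4)}, "ages"),
            ({"n_control_per_age": 0}, "cohort sizes"),
            ({"axes_per_mouse": 11}, "axes_per_mouse"),
        ],
    )
    def test_invalid_fields_named(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            generate_cohort(dataclasses.replace(SMALL, **kwargs))

    def test_family_proportions_must_close(self):
        mp = MicrobiotaParams()
        bad = dataclasses.replace(
            mp.families[0], prop_sev0=mp.families[0].prop_sev0 + 0.1
        )
        with pytest.raises(ValueError, match="sum to 1"):
            dataclasses.replace(
                mp, families=(bad,) + mp.families[1:]
            ).validate()

    def test_required_families_enforced(self):
        mp = MicrobiotaParams()
        with pytest.raises(ValueError, match="Rikenellaceae"):
            dataclasses.replace(mp, families=mp.families[:3]).validate()


class TestHistologyGenerator:
    def test_zero_noise_severity_zero_equals_control_means(self):
        params = HistologyParams(
            infiltration_sd=0.0, muscle_sd=0.0, ratio_sd=0.0, crypt_depth_sd=0.0
        )
        rng = np.random.default_rng(0)
        sec = generate_histology("m", 1.3, 0.0, params, rng, icc=0.9, strain="control")
        for a in sec.axes:
            assert a.inflammatory_cells == params.infiltration_mean
            assert a.muscle_thickness == params.muscle_mean
            assert a.villus_ratio == pytest.approx(params.ratio_mean)
        assert sec.crypt_abscess_count == 0

    def test_severity_shifts_in_disease_direction(self):
        params = HistologyParams()
        rng = np.random.default_rng(1)
        sick, healthy = [], []
        for i in range(200):
            b = rng.standard_normal()
            s1 = generate_histology("m", b, 1.0, params, rng)
            s0 = generate_histology("m", b, 0.0, params, rng)
            sick.append(np.mean([a.inflammatory_cells for a in s1.axes]))
            healthy.append(np.mean([a.inflammatory_cells for a in s0.axes]))
        assert np.mean(sick) > np.mean(healthy) + 6  # ~4 SD shift

    def test_icc_recovered_from_variance_components(self):
        """One-way ANOVA variance components on muscle thickness, 500 mice."""
        params = HistologyParams()
        rng = np.random.default_rng(3)
        vals = np.array(
            [
                [a.muscle_thickness for a in generate_histology(
                    f"m{i}", rng.standard_normal(), 0.0, params, rng, icc=0.9
                ).axes]
                for i in range(500)
            ]
        )
        n, k = vals.shape
        ms_between = k * np.var(vals.mean(axis=1), ddof=1)
        ms_within = np.mean(np.var(vals, axis=1, ddof=1))
        icc_hat = (ms_between - ms_within) / (ms_between + (k - 1) * ms_within)
        assert icc_hat == pytest.approx(0.9, abs=0.05)


class TestGelGenerator:
    def test_coupling_recovery_large_cohort(self):
        cfg = CohortConfig(n_control_per_age=1, n_case_per_age=34, seed=11)
        data = generate_cohort(cfg)
        cases = [m for m in data.mice if m.strain == "case"]
        sev = np.array([m.latent_severity for m in cases])
        r_ng = np.array([quantify_record(m.gel).r_ng for m in cases])
        r = np.corrcoef(sev, r_ng)[0, 1]
        assert r == pytest.approx(0.8, abs=0.15)

    def test_forty_fold_reduced_increase(self):
        """Mean reduced cryptdin rises ~9.82/0.23-fold from severity 0 to 1."""
        from ileodef.cohort import generate_gel

        gp = GelParams(lane_noise_ng_sd=0.0)
        rng = np.random.default_rng(5)
        r0 = np.mean(
            [quantify_record(generate_gel("s", 0.0, gp, rng, 0.3, 0.3)).r_ng
             for _ in range(4000)]
        )
        r1 = np.mean(
            [quantify_record(generate_gel("s", 1.0, gp, rng, 0.3, 0.3)).r_ng
             for _ in range(4000)]
        )
        assert r1 / r0 == pytest.approx(9.82 / 0.23, rel=0.10)

    def test_trp_minus_exceeds_trp_plus_in_expectation(self):
        """Total-cryptdin lanes are denser than trypsin-treated lanes on average."""
        import dataclasses

        rows = []
        for seed in range(30):
            data = generate_cohort(dataclasses.replace(SMALL, seed=seed))
            rows += [
                m.gel.trp_minus_intensity - m.gel.trp_plus_intensity for m in data.mice
            ]
        assert np.mean(rows) > 0

    def test_negative_reduced_amounts_occur_and_are_flagged(self):
        """Lane-level noise yields occasional negative per-sample r estimates."""
        import dataclasses

        flags = 0
        for seed in range(10):
            data = generate_cohort(dataclasses.replace(SMALL, seed=seed))
            flags += sum(
                quantify_record(m.gel).negative_r_flag
                for m in data.mice
                if m.latent_severity < 0.2
            )
        assert flags > 0


class TestMicrobiotaGenerator:
    def test_degenerate_dirichlet_zero_shift_equals_base(self):
        mp = MicrobiotaParams(concentration=float("inf"))
        _, _, fam_index = build_taxonomy(mp)
        props = otu_proportions(mp, 0.0, fam_index, rng=None)
        fam0 = np.array([f.prop_sev0 for f in mp.families])
        for fi in range(len(mp.families)):
            got = props[np.asarray(fam_index) == fi].sum()
            assert got == pytest.approx(fam0[fi], abs=1e-12)
        assert props.sum() == pytest.approx(1.0, abs=1e-12)

    def test_counts_sum_to_library_size(self):
        data = generate_cohort(SMALL)
        assert np.all(data.otu_table.sample_totals > 0)

    def test_severity_shift_directions_recovered(self):
        mp = MicrobiotaParams()
        _, _, fam_index = build_taxonomy(mp)
        fam_index = np.asarray(fam_index)
        rng = np.random.default_rng(2)
        names = [f.name for f in mp.families]
        bact = names.index("Bacteroidaceae")
        means = {}
        for sev in (0.0, 1.0):
            shares = []
            for _ in range(50):
                p = otu_proportions(mp, sev, fam_index, rng)
                shares.append(p[fam_index == bact].sum())
            means[sev] = np.mean(shares)
        assert means[1.0] > means[0.0]

    def test_richness_falls_with_severity(self):
        from ileodef.cohort import generate_microbiota

        mp = MicrobiotaParams()
        _, _, fam_index = build_taxonomy(mp)
        rng = np.random.default_rng(4)
        obs = {s: [] for s in (0.0, 1.0)}
        for sev in obs:
            for _ in range(50):
                c = generate_microbiota(sev, mp, rng, fam_index)
                obs[sev].append(int((c > 0).sum()))
        assert np.mean(obs[1.0]) < np.mean(obs[0.0]) - 10

    def test_tree_covers_all_otus(self):
        data = generate_cohort(SMALL)
        assert set(data.tree.leaf_names) == set(data.otu_table.otu_ids)
        assert np.all(data.tree.edge_lengths >= 0)


class TestNullSoundness:
    def test_zero_effects_strain_uninformative(self):
        """With every severity effect off, strain labels carry no signal."""
        variables = {
            "infiltration": lambda m: np.mean(
                [a.inflammatory_cells for a in m.section.axes]
            ),
            "ratio": lambda m: np.mean([a.villus_ratio for a in m.section.axes]),
            "r_ng": lambda m: quantify_record(m.gel).r_ng,
            "richness": None,  # handled from the OTU table
        }
        rejections = {v: 0 for v in variables}
        for seed in range(50):
            cfg = CohortConfig.null(
                n_control_per_age=4, n_case_per_age=4, ages=(4,), seed=1000 + seed
            )
            data = generate_cohort(cfg)
            ctrl = [m for m in data.mice if m.strain == "control"]
            case = [m for m in data.mice if m.strain == "case"]
            for name, fn in variables.items():
                if fn is None:
                    idx = {s: i for i, s in enumerate(data.otu_table.sample_ids)}
                    a = [int((data.otu_table.counts[idx[m.mouse_id]] > 0).sum()) for m in ctrl]
                    b = [int((data.otu_table.counts[idx[m.mouse_id]] > 0).sum()) for m in case]
                else:
                    a = [fn(m) for m in ctrl]
                    b = [fn(m) for m in case]
                p = mann_whitney_u(a, b).p_two_sided
                rejections[name] += int(p < 0.01)
        for name, count in rejections.items():
            assert count <= 3, (name, count)  # binomial(50, 0.01) upper tail
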