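import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from immunotrack import (
    CellMap,
    CountPanel,
    UnavailableMetricError,
    ValidationError,
    delta_ct_expression,
    gen_cell_map,
    h_score,
    panel_qc_normalize,
    proximity_index,
)


def make_panel(n_samples=4, seed=0, binding_density=None, n_hk=6):
    rng = np.random.default_rng(seed)
    probes = (
        [f"NEG_{i}" for i in range(4)]
        + [f"POS_{i}" for i in range(6)]
        + [f"HK_{i}" for i in range(n_hk)]
        + [f"GENE_{i}" for i in range(20)]
    )
    classes = ["negative"] * 4 + ["positive"] * 6 + ["housekeeping"] * n_hk + ["endogenous"] * 20
    conc = [0.125, 0.5, 2, 8, 32, 128]
    samples = [f"S{i}" for i in range(n_samples)]
    counts = pd.DataFrame(index=probes, columns=samples, dtype=float)
    for s in samples:
        counts.loc[[p for p in probes if p.startswith("NEG")], s] = rng.poisson(12, 4)
        counts.loc[[p for p in probes if p.startswith("POS")], s] = [
            60 * c + rng.normal(0, 1) for c in conc
        ]
        counts.loc[[p for p in probes if p.startswith("HK")], s] = rng.poisson(800, n_hk)
        counts.loc[[p for p in probes if p.startswith("GENE")], s] = rng.poisson(300, 20)
    counts = counts.clip(lower=0)
    bd = pd.Series(
        binding_density if binding_density is not None else [1.0] * n_samples, index=samples
    )
    return CountPanel(
        counts=counts,
        probe_class=pd.Series(classes, index=probes),
        positive_concentration=pd.Series(conc, index=[f"POS_{i}" for i in range(6)]),
        binding_density=bd,
    )


class TestPanelQcNormalize:
    def test_background_threshold_rule(self):
        panel = make_panel()
        # force negatives to 10, 12, 14, 12 -> mean 12, sd ~1.63; use 3 negatives
        panel.counts.loc[["NEG_0", "NEG_1", "NEG_2", "NEG_3"], "S0"] = [10, 12, 14, 12]
        panel.counts.loc["GENE_0", "S0"] = 15.0
        normalized, qc = panel_qc_normalize(panel)
        neg = np.array([10, 12, 14, 12.0])
        threshold = neg.mean() + 2 * neg.std(ddof=1)
        assert 15.0 < threshold
        assert normalized.loc["GENE_0", "S0"] == 0.0

    def test_binding_density_failure(self):
        panel = make_panel(binding_density=[2.5, 1.0, 1.0, 1.0])
        normalized, qc = panel_qc_normalize(panel)
        assert not qc.loc["S0", "pass"]
        assert "S0" not in normalized.columns

    def test_perfect_linearity_passes(self):
        panel = make_panel()
        conc = panel.positive_concentration
        for s in panel.counts.columns:
            panel.counts.loc[conc.index, s] = 55 * conc.values
        _, qc = panel_qc_normalize(panel)
        assert (qc["positive_r2"] > 0.999).all()
        assert qc["linearity_pass"].all()

    def test_nonlinear_positives_fail(self):
        panel = make_panel()
        rng = np.random.default_rng(1)
        panel.counts.loc[panel.positive_concentration.index, "S1"] = rng.permutation(
            [5, 5000, 7, 4000, 6, 3000]
        )
        _, qc = panel_qc_normalize(panel)
        assert not qc.loc["S1", "linearity_pass"]

    def test_fixed_reference_scale_invariance(self):
        # references near the panel's own scale keep factors inside QC range;
        # 3 housekeeping probes pin the stable set so the HK factor cancels
        # any per-sample scalar exactly
        panel = make_panel(n_hk=3)
        norm1, qc1 = panel_qc_normalize(
            panel, positive_reference=240.0, housekeeping_reference=800.0
        )
        assert qc1["pass"].all()
        panel2 = make_panel(n_hk=3)
        panel2.counts["S1"] = panel2.counts["S1"] * 1.7
        norm2, qc2 = panel_qc_normalize(
            panel2, positive_reference=240.0, housekeeping_reference=800.0
        )
        endo = [p for p in norm1.index if p.startswith("GENE")]
        assert np.allclose(norm1.loc[endo, "S1"], norm2.loc[endo, "S1"], atol=1e-9)

    def test_default_reference_preserves_between_sample_ratios(self):
        panel = make_panel(n_hk=3)
        norm1, _ = panel_qc_normalize(panel)
        panel2 = make_panel(n_hk=3)
        panel2.counts["S1"] = panel2.counts["S1"] * 1.5
        norm2, _ = panel_qc_normalize(panel2)
        endo = [p for p in norm1.index if p.startswith("GENE")]
        r1 = norm1.loc[endo, "S1"] / norm1.loc[endo, "S0"]
        r2 = norm2.loc[endo, "S1"] / norm2.loc[endo, "S0"]
        assert np.allclose(r1, r2, rtol=1e-9)

    def test_too_few_negative_probes_rejected(self):
        panel = make_panel()
        with pytest.raises(ValidationError):
            CountPanel(
                counts=panel.counts.drop(index=["NEG_0", "NEG_1"]),
                probe_class=panel.probe_class.drop(["NEG_0", "NEG_1"]),
                positive_concentration=panel.positive_concentration,
                binding_density=panel.binding_density,
            )


class TestDeltaCt:
    def test_fold_change_formula(self):
        assert delta_ct_expression(25, 20, 27, 20) == pytest.approx(4.0)

    def test_control_vs_itself_is_one(self):
        assert delta_ct_expression(30, 22, 30, 22) == 1.0

    def test_no_amplification_maps_to_ceiling(self):
        fold = delta_ct_expression(np.nan, 20, 30, 20)
        assert fold == pytest.approx(2.0 ** -(20 - 10))

    def test_ct_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            delta_ct_expression(45, 20, 30, 20)


class TestHScore:
    @pytest.mark.parametrize(
        "s,m,w,expected", [(10, 20, 30, 100), (100, 0, 0, 300), (0, 0, 0, 0)]
    )
    def test_formula(self, s, m, w, expected):
        assert h_score(s, m, w) == expected

    def test_sum_over_100_rejected(self):
        with pytest.raises(ValidationError):
            h_score(60, 30, 20)

    @given(
        st.floats(min_value=0, max_value=16),
        st.floats(min_value=0, max_value=16),
        st.floats(min_value=0, max_value=16),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_linear(self, s, m, w):
        # max 16 per component keeps the doubled sum (<=96) inside 100
        val = h_score(s, m, w)
        assert 0 <= val <= 300
        assert h_score(2 * s, 2 * m, 2 * w) == pytest.approx(2 * val)


def brute_force_proximity(cell_map, cutoff):
    cd8 = cell_map.coords_of("CD8")
    pdl1 = cell_map.coords_of("PDL1")
    if len(pdl1) == 0:
        return 0.0
    d = cdist(cd8, pdl1)
    return 100.0 * np.mean((d <= cutoff).any(axis=1))


class TestProximityIndex:
    def test_all_within_cutoff(self):
        cm = gen_cell_map(30, 30, clustering="attract", attract_radius_um=5, seed=1)
        assert proximity_index(cm, 20) == 100.0

    def test_no_pdl1_cells(self):
        cm = gen_cell_map(10, 0, seed=2)
        assert proximity_index(cm, 40) == 0.0

    def test_direct_count(self):
        cm = CellMap(
            x_um=np.array([0.0, 0.0, 10.0, 50.0]),
            y_um=np.zeros(4),
            phenotype=np.array(["PDL1", "other", "CD8", "CD8"], dtype=object),
        )
        assert proximity_index(cm, 20) == 50.0

    def test_no_cd8_unavailable(self):
        cm = CellMap(np.array([1.0]), np.array([1.0]), np.array(["PDL1"], dtype=object))
        with pytest.raises(UnavailableMetricError):
            proximity_index(cm, 20)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        cm = gen_cell_map(80, 40, clustering="none", seed=seed)
        for cutoff in (20, 40, 60, 80):
            assert proximity_index(cm, cutoff) == brute_force_proximity(cm, cutoff)

    def test_nondecreasing_in_cutoff_and_saturates(self):
        cm = gen_cell_map(50, 25, field_um=500, seed=4)
        values = [proximity_index(cm, c) for c in (20, 40, 60, 80)]
        assert values == sorted(values)
        diameter = 500 * np.sqrt(2) + 1
        assert proximity_index(cm, diameter) == 100.0
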