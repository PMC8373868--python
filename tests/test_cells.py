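import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invasim import (
    CellPopulation,
    Fate,
    FateProbabilities,
    ModelParameters,
    TumorCell,
    compute_fate_probabilities,
    draw_fate,
    update_emt_score,
)
from invasim.cells import (
    choose_mutation_pathway,
    emt_score_step,
    fate_probability_matrix,
    update_mutation_machinery,
)


def cell_strategy():
    return st.builds(
        TumorCell,
        prolif_mut=st.booleans(),
        apop_mut=st.booleans(),
        ie_mut=st.booleans(),
        emt_score=st.floats(0, 1),
        mesenchymal=st.booleans(),
        mut_prob=st.floats(0, 0.1),
    )


def params_strategy():
    return st.builds(
        ModelParameters,
        p=st.floats(0.01, 0.9),
        d_c=st.floats(0.01, 0.9),
        delta_p=st.floats(0, 1),
        delta_a=st.floats(0, 1),
        delta_ie=st.floats(0, 1),
        delta_mga=st.floats(0, 1),
        delta_mie=st.floats(0, 1),
        e_nk=st.floats(0, 1),
        e_ctl=st.floats(0, 1),
        k_0=st.floats(1, 1e3),
        k_1=st.floats(1, 1e3),
        k_2=st.floats(1, 1e3),
        delta_mut_baseline=st.floats(0, 1),
    )


class TestFateProbabilities:
    def test_unmutated_cell_no_crowding_no_effectors(self):
        # vanishing-crowding limit: proliferation at its baseline p
        p = ModelParameters(p=0.2, d_c=0.1, k_0=1e12)
        fp = compute_fate_probabilities(TumorCell(), 1, 0.0, 0.0, 0.0, p)
        assert fp.rho_p == pytest.approx(0.2, abs=1e-9)
        assert fp.rho_a == 0.1
        assert fp.rho_nk == 0.0 and fp.rho_ctl == 0.0
        assert fp.rho_r == pytest.approx(0.7, abs=1e-9)

    def test_proliferation_hand_evaluation(self):
        # p(1+dP*DP)(1-z*DMGA)/(1+N/K0) = 0.2*1.5*0.75*0.5
        p = ModelParameters(p=0.2, delta_p=0.5, delta_mga=0.25, k_0=100.0)
        cell = TumorCell(prolif_mut=True, mesenchymal=True, emt_score=0.9)
        fp = compute_fate_probabilities(cell, 100, 0.0, 0.0, 0.0, p)
        assert fp.rho_p == pytest.approx(0.1125, abs=1e-12)

    def test_nk_clearance_hand_evaluation(self):
        p = ModelParameters(p=0.2, d_c=0.1, k_1=100.0, e_nk=0.5,
                            delta_ie=0.9)
        cell = TumorCell(prolif_mut=True)  # mutated, immunogenicity 1
        fp = compute_fate_probabilities(cell, 100, 50.0, 0.0, 0.0, p)
        assert fp.rho_nk == pytest.approx(50.0 / 51.0 * 0.5, abs=1e-9)

    def test_complete_mesenchymal_evasion(self):
        p = ModelParameters(delta_mie=1.0)
        cell = TumorCell(prolif_mut=True, mesenchymal=True, emt_score=0.9)
        fp = compute_fate_probabilities(cell, 50, 1e3, 1e3, 0.0, p)
        assert fp.rho_nk == 0.0 and fp.rho_ctl == 0.0

    @given(cell=cell_strategy(), params=params_strategy(),
           n_tumor=st.integers(1, 2000),
           n_nk=st.floats(0, 500), n_ctl=st.floats(0, 500),
           n_treg=st.floats(0, 500))
    @settings(max_examples=200, deadline=None)
    def test_conservation_and_bounds(self, cell, params, n_tumor, n_nk,
                                     n_ctl, n_treg):
        fp = compute_fate_probabilities(cell, n_tumor, n_nk, n_ctl, n_treg,
                                        params)
        arr = fp.as_array()
        assert np.all(arr >= 0) and np.all(arr <= 1)
        assert abs(arr.sum() - 1.0) <= 1e-12

    @pytest.mark.parametrize(
        "kw_lo,kw_hi,field",
        [
            # rho_p non-increasing in crowding and MGA; non-decreasing in DP
            (dict(n_tumor=50), dict(n_tumor=500), "rho_p"),
        ],
    )
    def test_rho_p_monotone_in_crowding(self, kw_lo, kw_hi, field):
        p = ModelParameters()
        cell = TumorCell()
        lo = compute_fate_probabilities(cell, kw_lo["n_tumor"], 0, 0, 0, p)
        hi = compute_fate_probabilities(cell, kw_hi["n_tumor"], 0, 0, 0, p)
        assert getattr(hi, field) <= getattr(lo, field)

    def test_monotonicity_in_effect_sizes(self):
        base = ModelParameters()
        mes = TumorCell(prolif_mut=True, mesenchymal=True, emt_score=0.9)
        rho_p = [
            compute_fate_probabilities(
                mes, 100, 0, 0, 0, base.replace(delta_mga=g)
            ).rho_p
            for g in (0.0, 0.3, 0.8)
        ]
        assert rho_p[0] >= rho_p[1] >= rho_p[2]
        rho_nk = [
            compute_fate_probabilities(
                mes, 100, 50, 0, t, base.replace(delta_mie=0.2)
            ).rho_nk
            for t in (0.0, 20.0, 200.0)
        ]
        assert rho_nk[0] >= rho_nk[1] >= rho_nk[2]

    def test_treg_suppression_and_unmutated_invisible(self):
        p = ModelParameters(delta_mut_baseline=0.0)
        fp = compute_fate_probabilities(TumorCell(), 100, 50, 50, 0, p)
        assert fp.rho_nk == 0.0 and fp.rho_ctl == 0.0

    def test_invalid_inputs_raise(self):
        p = ModelParameters()
        with pytest.raises(ValueError):
            compute_fate_probabilities(TumorCell(), 0, 0, 0, 0, p)
        with pytest.raises(ValueError):
            compute_fate_probabilities(TumorCell(), 10, -1, 0, 0, p)

    def test_scalar_matches_vectorized(self, rng):
        p = ModelParameters()
        cells = [
            TumorCell(
                prolif_mut=bool(rng.integers(2)),
                apop_mut=bool(rng.integers(2)),
                ie_mut=bool(rng.integers(2)),
                emt_score=float(rng.random()),
                mesenchymal=bool(rng.integers(2)),
                mut_prob=float(rng.random() * 0.01),
            )
            for _ in range(20)
        ]
        pop = CellPopulation.from_cells(cells)
        mat = fate_probability_matrix(pop, 150, 30.0, 10.0, 5.0, p)
        for i, cell in enumerate(cells):
            fp = compute_fate_probabilities(cell, 150, 30.0, 10.0, 5.0, p)
            np.testing.assert_allclose(mat[i], fp.as_array(), rtol=0, atol=0)


class TestDrawFate:
    def test_degenerate_distribution(self, rng):
        probs = FateProbabilities(1.0, 0.0, 0.0, 0.0, 0.0)
        assert all(draw_fate(probs, rng) is Fate.PROLIFERATE for _ in range(50))

    def test_reproducible_given_stream_state(self):
        probs = FateProbabilities(0.3, 0.2, 0.1, 0.1, 0.3)
        a = [draw_fate(probs, np.random.default_rng(5)) for _ in range(1)]
        b = [draw_fate(probs, np.random.default_rng(5)) for _ in range(1)]
        assert a == b

    def test_empirical_frequencies(self):
        probs = FateProbabilities(0.3, 0.2, 0.1, 0.1, 0.3)
        rng = np.random.default_rng(77)
        n = 100_000
        counts = np.bincount(
            [int(draw_fate(probs, rng)) for _ in range(n)], minlength=5
        )
        for k, pk in enumerate(probs.as_array()):
            se = np.sqrt(pk * (1 - pk) / n)
            assert abs(counts[k] / n - pk) < 4 * se

    def test_invalid_distribution_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_fate(FateProbabilities(0.5, 0.2, 0.1, 0.1, 0.3), rng)


class TestMutationMachinery:
    def test_non_mutating_proliferation_increments(self):
        p = ModelParameters()
        cell = TumorCell(mut_prob=0.001)
        out, acquired = update_mutation_machinery(
            cell, p, np.random.default_rng(3)
        )
        if not acquired:
            assert out.mut_prob == pytest.approx(0.001 + 1e-4, abs=0)

    def test_mutating_proliferation_resets(self, rng):
        p = ModelParameters()
        cell = TumorCell(mut_prob=1.0)  # certain acquisition
        out, acquired = update_mutation_machinery(cell, p, rng)
        assert acquired
        assert out.mut_prob == 0.0
        assert out.mutated

    def test_consecutive_ladder(self):
        # 37 non-mutating proliferations from birth: 37 x 1e-4
        p = ModelParameters()
        rng = np.random.default_rng(11)
        cell = TumorCell()
        for _ in range(37):
            cell, acquired = update_mutation_machinery(cell, p, rng)
            assert not acquired  # P(acquire) <= 3.7e-3 per step; seed-checked
        assert cell.mut_prob == pytest.approx(0.0037, abs=1e-15)

    def test_forced_pathway_choice(self, rng):
        cell = TumorCell(prolif_mut=True, apop_mut=True)
        out = choose_mutation_pathway(cell, rng)
        assert out.ie_mut

    def test_saturated_cell_unchanged(self, rng):
        cell = TumorCell(prolif_mut=True, apop_mut=True, ie_mut=True)
        assert choose_mutation_pathway(cell, rng) == cell

    def test_uniform_choice_among_open_pathways(self):
        rng = np.random.default_rng(13)
        n = 10_000
        counts = {"prolif_mut": 0, "apop_mut": 0, "ie_mut": 0}
        for _ in range(n):
            out = choose_mutation_pathway(TumorCell(), rng)
            for name in counts:
                counts[name] += getattr(out, name)
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for name in counts:
            assert abs(counts[name] / n - 1 / 3) < 4 * se


class TestEMTScore:
    def test_zero_tgfb_decays_to_epithelial(self):
        p = ModelParameters(emt_decay=0.2)
        cell = TumorCell(emt_score=0.9, mesenchymal=True)
        scores = []
        for _ in range(60):
            cell = update_emt_score(cell, 0.0, p)
            scores.append(cell.emt_score)
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert cell.emt_score < 1e-4
        assert not cell.mesenchymal

    def test_fixed_point_at_constant_tgfb(self):
        p = ModelParameters(emt_gain=0.3, emt_decay=0.05, k_tau=1.0)
        tau = 2.0
        g = p.emt_gain * tau / (tau + p.k_tau)
        expected = g / (g + p.emt_decay)
        cell = TumorCell()
        for _ in range(500):
            cell = update_emt_score(cell, tau, p)
        assert cell.emt_score == pytest.approx(expected, abs=1e-8)

    def test_threshold_is_strict(self):
        # a score landing exactly on t_mes stays epithelial
        p = ModelParameters(emt_gain=0.0, emt_decay=0.0, t_mes=0.5)
        cell = update_emt_score(TumorCell(emt_score=0.5), 0.0, p)
        assert cell.emt_score == 0.5
        assert not cell.mesenchymal
        above = update_emt_score(TumorCell(emt_score=0.5000001), 0.0, p)
        assert above.mesenchymal

    def test_negative_tgfb_rejected(self):
        with pytest.raises(ValueError):
            emt_score_step(0.5, -1.0, ModelParameters())

    @given(taus=st.lists(st.floats(0, 1e6), min_size=1, max_size=100),
           start=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_score_bounded_under_arbitrary_inputs(self, taus, start):
        p = ModelParameters(emt_gain=0.9, emt_decay=0.9)
        score = start
        for tau in taus:
            score = float(emt_score_step(score, tau, p))
            assert 0.0 <= score <= 1.0
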