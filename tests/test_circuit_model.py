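import numpy as np
import pandas as pd
import pytest

from alsim.circuit_model import (
    NeuronRoster,
    SensitivityConfig,
    assign_ln_polarity,
    assign_pn_polarity,
    build_weight_matrix,
    ln_innervation_counts,
    load_circuit,
)

from conftest import toy_roster


def _roster_df(rows):
    return pd.DataFrame(rows, columns=["id", "cell_class", "glomerulus", "polarity"])


def _edges_df(rows):
    return pd.DataFrame(rows, columns=["pre_id", "post_id", "synapse_count"])


class TestLoadCircuit:
    def test_toy_counts_at_stated_positions(self):
        roster, counts = load_circuit(
            _roster_df([("a", "ORN", "DA1", 1), ("b", "uPN", "DA1", None), ("c", "LN", None, None)]),
            _edges_df([("a", "b", 7), ("c", "b", 3)]),
        )
        assert counts.shape == (3, 3)
        assert np.count_nonzero(counts) == 2
        ia, ib, ic = [list(roster.ids).index(x) for x in "abc"]
        assert counts[ia, ib] == 7 and counts[ic, ib] == 3

    def test_non_olfactory_glomeruli_dropped(self):
        roster, counts = load_circuit(
            _roster_df([("a", "ORN", "VP2", 1), ("b", "ORN", "DA1", 1), ("p", "uPN", "DA1", None)]),
            _edges_df([("a", "p", 4), ("b", "p", 2)]),
        )
        assert "a" not in roster.ids and "b" in roster.ids
        assert counts.sum() == 2  # the VP2 edge vanished with its neuron

    def test_empty_edges_gives_zero_matrix(self):
        _, counts = load_circuit(
            _roster_df([("a", "ORN", "DA1", 1), ("p", "uPN", "DA1", None)]),
            _edges_df([]),
        )
        assert counts.shape == (2, 2) and not counts.any()

    def test_unknown_edge_id_raises(self):
        with pytest.raises(ValueError, match="ghost"):
            load_circuit(
                _roster_df([("a", "ORN", "DA1", 1), ("p", "uPN", "DA1", None)]),
                _edges_df([("a", "ghost", 1)]),
            )

    def test_duplicate_roster_id_raises(self):
        with pytest.raises(ValueError, match="duplicate"):
            load_circuit(
                _roster_df([("a", "ORN", "DA1", 1), ("a", "ORN", "DA1", 1)]),
                _edges_df([]),
            )


def _ln_roster(n_ln, n_glom=10, orns_per=2):
    rows = []
    for g in range(n_glom):
        for k in range(orns_per):
            rows.append((f"g{g}orn{k}", "ORN", f"G{g}", 1.0))
    for k in range(n_ln):
        rows.append((f"ln{k:03d}", "LN", None, np.nan))
    roster = toy_roster(rows)
    n = len(roster)
    rng = np.random.default_rng(0)
    counts = np.zeros((n, n))
    # every LN touches a random subset of ORNs so innervation counts vary
    for i in roster.index_of("LN"):
        picks = rng.choice(roster.index_of("ORN"), size=rng.integers(1, n_glom * orns_per), replace=False)
        counts[picks, i] = 1.0
    return roster, counts


class TestLnPolarity:
    def test_197_lns_give_31_elns(self):
        roster, counts = _ln_roster(197)
        out = assign_ln_polarity(roster, counts, eln_iln_ratio=5.4, seed=0)
        pol = out.polarity[out.index_of("LN")]
        assert int((pol == 1).sum()) == 31
        assert int((pol == -1).sum()) == 166

    def test_64_lns_give_10_elns(self):
        roster, counts = _ln_roster(64)
        out = assign_ln_polarity(roster, counts, seed=0)
        assert int((out.polarity[out.index_of("LN")] == 1).sum()) == 10

    def test_no_lns_no_error(self):
        roster = toy_roster([("a", "ORN", "DA1", 1.0)])
        out = assign_ln_polarity(roster, np.zeros((1, 1)), seed=0)
        assert len(out) == 1

    def test_nonpositive_ratio_raises(self):
        roster, counts = _ln_roster(10)
        with pytest.raises(ValueError):
            assign_ln_polarity(roster, counts, eln_iln_ratio=0.0, seed=0)

    def test_seed_reproducibility(self):
        roster, counts = _ln_roster(40)
        a = assign_ln_polarity(roster, counts, seed=7).polarity
        b = assign_ln_polarity(roster, counts, seed=7).polarity
        assert np.array_equal(a, b, equal_nan=True)

    def test_bottom_half_never_excitatory_and_frequency(self):
        roster, counts = _ln_roster(20)
        innerv = ln_innervation_counts(roster, counts)
        ln_ids = roster.ids[roster.index_of("LN")]
        order = sorted(ln_ids, key=lambda i: (-innerv[i], i))
        top = set(order[:10])
        n_eln = 3  # round(20 / 6.4)
        hits = {i: 0 for i in ln_ids}
        n_seeds = 1000
        for s in range(n_seeds):
            out = assign_ln_polarity(roster, counts, seed=s)
            pol = out.polarity[out.index_of("LN")]
            for i, p in zip(ln_ids, pol):
                if p == 1:
                    hits[i] += 1
                    assert i in top, "bottom-half LN assigned excitatory"
        p_sel = n_eln / len(top)
        sd = np.sqrt(p_sel * (1 - p_sel) / n_seeds)
        for i in top:
            assert abs(hits[i] / n_seeds - p_sel) < 3 * sd + 0.01


class TestPnPolarity:
    def test_fully_annotated_ignores_seed(self):
        roster = toy_roster([("m1", "mPN", None, np.nan), ("m2", "mPN", None, np.nan)])
        known = {"m1": "cholinergic", "m2": "GABAergic"}
        for seed in (0, 1):
            out = assign_pn_polarity(roster, known, seed=seed)
            assert out.polarity.tolist() == [1.0, -1.0]

    def test_unanimous_fraction_forces_polarity(self):
        rows = [("k", "mPN", None, np.nan)] + [(f"u{i}", "mPN", None, np.nan) for i in range(20)]
        out = assign_pn_polarity(toy_roster(rows), {"k": "cholinergic"}, seed=3)
        assert (out.polarity == 1.0).all()

    def test_binomial_count_at_half_fraction(self):
        rows = [("k1", "uPN", "X1", np.nan), ("k2", "uPN", "X1", np.nan)]
        rows += [(f"u{i}", "uPN", "X1", np.nan) for i in range(10_000)]
        known = {"k1": "cholinergic", "k2": "GABAergic"}
        out = assign_pn_polarity(toy_roster(rows), known, seed=11)
        n_exc = int((out.polarity == 1.0).sum()) - 1  # subtract the known cholinergic
        assert abs(n_exc - 5000) < 3 * 50

    def test_missing_fraction_raises(self):
        roster = toy_roster([("u", "mPN", None, np.nan)])
        with pytest.raises(ValueError, match="fraction"):
            assign_pn_polarity(roster, {}, seed=0)


class TestWeightMatrix:
    def test_sign_and_scale(self, three_neuron_circuit):
        roster, counts = three_neuron_circuit
        w = build_weight_matrix(roster, counts, SensitivityConfig())
        assert w.effective_weights[0, 1] == pytest.approx(10 * 0.4)   # ORN -> PN
        assert w.effective_weights[2, 1] == pytest.approx(-5 * 0.4)   # iLN -> PN

    def test_identity_limit(self, fixture_parts):
        roster, counts, _ = fixture_parts
        tab = roster.table.copy()
        tab["polarity"] = 1.0
        all_exc = NeuronRoster(tab)
        unit = SensitivityConfig(a_orn=1, a_eln=1, a_iln=1, a_pn=1)
        w = build_weight_matrix(all_exc, counts, unit)
        assert np.array_equal(w.effective_weights, counts)

    def test_sparsity_pattern_and_inhibitory_rows(self, fixture_weights):
        w = fixture_weights
        assert np.array_equal(w.effective_weights != 0, w.raw_counts != 0)
        inh = w.roster.polarity < 0
        assert (w.effective_weights[inh] <= 0).all()

    def test_scaling_commutes_with_sign_flip(self, three_neuron_circuit):
        roster, counts = three_neuron_circuit
        sens = SensitivityConfig()
        w = build_weight_matrix(roster, counts, sens)
        # manual alternative order: scale columns first, then sign rows
        cls = roster.cell_class
        pol = roster.polarity
        col = np.where(cls == "ORN", sens.a_orn, np.where(cls == "LN", sens.a_iln, sens.a_pn))
        manual = (counts * col[None, :]) * pol[:, None]
        assert np.allclose(manual, w.effective_weights)

    def test_unassigned_polarity_raises(self):
        roster = toy_roster([("p", "uPN", "DA1", np.nan)])
        with pytest.raises(ValueError, match="polarity"):
            build_weight_matrix(roster, np.zeros((1, 1)))
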