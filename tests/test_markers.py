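"""Pairwise DE, marker intersection, repertoire statistics, LR pairing."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from psn_atlas.exceptions import InputError
from psn_atlas.markers import (
    annotate_subtypes,
    dotplot_stats,
    intersect_markers,
    pair_ligand_receptor,
    pairwise_de,
    prevalence_screen,
    scale_abundance,
)


def two_group_matrix(xa, xb, gene_names=None):
    """Cells x genes AnnData with labels a/b from per-group value arrays."""
    X = np.vstack([xa, xb])
    n_genes = X.shape[1]
    var = pd.DataFrame(index=gene_names or [f"G{i}" for i in range(n_genes)])
    obs = pd.DataFrame(index=[f"c{i}" for i in range(len(X))])
    labels = pd.Series(
        ["a"] * len(xa) + ["b"] * len(xb), index=obs.index, dtype=object
    )
    return ad.AnnData(X=X, obs=obs, var=var), labels


class TestPairwiseDE:
    def test_planted_marker_detected(self, rng):
        base = rng.lognormal(2, 0.5, size=(15, 50))
        up = base.copy()
        up[:, 0] *= 8.0
        m, lab = two_group_matrix(up, base)
        res = pairwise_de(m, lab)
        hit = res[(res.subtype_a == "a") & (res.gene == "G0")]
        assert float(hit.q_value.iloc[0]) < 0.01
        assert float(hit.effect.iloc[0]) > 2.0

    def test_constant_gene_p_one(self, rng):
        base = rng.lognormal(2, 0.5, size=(10, 5))
        base[:, 2] = 7.0
        other = rng.lognormal(2, 0.5, size=(10, 5))
        other[:, 2] = 7.0
        m, lab = two_group_matrix(base, other)
        res = pairwise_de(m, lab)
        assert (res[res.gene == "G2"].p_value == 1.0).all()

    def test_symmetry_effect_negated_p_preserved(self, rng):
        m, lab = two_group_matrix(
            rng.lognormal(2, 0.5, size=(12, 20)), rng.lognormal(2.5, 0.5, size=(9, 20))
        )
        res = pairwise_de(m, lab)
        ab = res[res.subtype_a == "a"].set_index("gene")
        ba = res[res.subtype_a == "b"].set_index("gene")
        assert np.allclose(ab.effect, -ba.loc[ab.index].effect)
        assert np.allclose(ab.p_value, ba.loc[ab.index].p_value)

    def test_null_type_one_error_controlled(self):
        n_sig = n_tot = n_q = 0
        for sim in range(20):
            rng = np.random.default_rng(1000 + sim)
            m, lab = two_group_matrix(
                rng.lognormal(2, 0.5, size=(15, 500)), rng.lognormal(2, 0.5, size=(15, 500))
            )
            res = pairwise_de(m, lab)
            half = res[res.subtype_a == "a"]
            n_sig += (half.p_value < 0.05).sum()
            n_q += (half.q_value >= 0.05).sum()
            n_tot += len(half)
        assert n_sig / n_tot <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tot)
        assert n_q / n_tot >= 0.99

    def test_tiny_group_skipped_with_record(self, rng):
        m, lab = two_group_matrix(
            rng.lognormal(2, 0.5, size=(10, 5)), rng.lognormal(2, 0.5, size=(10, 5))
        )
        lab.iloc[-1] = "tiny"
        res = pairwise_de(m, lab)
        assert "tiny" in res.attrs["skipped"]


def synthetic_results(n_sub=4, genes=("G0", "G1")):
    """Hand-built all-pairs DE frame where G0 is up in s0 vs everyone and a
    certified sentinel gene powers every pair."""
    subs = [f"s{i}" for i in range(n_sub)]
    rows = []
    for a in subs:
        for b in subs:
            if a == b:
                continue
            for g in genes:
                up = g == "G0" and a == "s0"
                down = g == "G0" and b == "s0"
                rows.append(
                    dict(
                        gene=g,
                        subtype_a=a,
                        subtype_b=b,
                        effect=2.0 if up else (-2.0 if down else 0.0),
                        p_value=1e-5 if (up or down) else 0.8,
                        q_value=1e-4 if (up or down) else 0.9,
                        n_a=10,
                        n_b=10,
                        p_floor=1e-6,
                    )
                )
            # sentinel certifying the pair as powered
            rows.append(
                dict(gene="SENT", subtype_a=a, subtype_b=b, effect=0.0,
                     p_value=1e-6, q_value=1e-5, n_a=10, n_b=10, p_floor=1e-6)
            )
    return pd.DataFrame(rows)


class TestIntersection:
    def test_gene_up_against_all_others_is_enriched(self):
        mt = intersect_markers(synthetic_results())
        assert list(mt[mt.gene == "G0"].subtype) == ["s0"]

    def test_one_failed_comparison_vetoes(self):
        res = synthetic_results()
        idx = (res.gene == "G0") & (res.subtype_a == "s0") & (res.subtype_b == "s3")
        res.loc[idx, ["q_value", "p_value"]] = [0.9, 0.8]
        mt = intersect_markers(res)
        assert "G0" not in set(mt.gene)

    def test_missing_pair_is_an_error(self):
        res = synthetic_results()
        res = res[~((res.subtype_a == "s1") & (res.subtype_b == "s2"))]
        with pytest.raises(InputError, match="s1"):
            intersect_markers(res)

    def test_no_gene_enriched_twice(self, kept_atlas):
        truth = kept_atlas.obs.truth_label
        lab = truth[truth != "PSN-H"]
        mt = intersect_markers(pairwise_de(kept_atlas[lab.index], lab))
        assert not mt.gene.duplicated().any()

    def test_planted_markers_recovered_without_false_positives(self, kept_atlas, default_atlas):
        truth = kept_atlas.obs.truth_label
        lab = truth[truth != "PSN-H"]
        mt = intersect_markers(pairwise_de(kept_atlas[lab.index], lab))
        gc = default_atlas.var.gene_class
        for s, d in mt.groupby("subtype"):
            planted = set(gc.index[gc == f"marker:{s}"])
            got = set(d.gene)
            assert not (got - planted), f"false markers for {s}: {got - planted}"
            assert len(got & planted) >= 0.9 * len(planted)
        # every sufficiently large population is recovered
        big = {s for s in lab.unique() if (lab == s).sum() >= 5}
        assert big <= set(mt.subtype.unique())


class TestDotplotAndScreens:
    def test_hand_arithmetic(self):
        m, lab = two_group_matrix(np.array([[0.0], [3.0], [7.0]]), np.array([[1.0]]))
        st = dotplot_stats(m, lab, ["G0"])
        a = st[st.subtype == "a"].iloc[0]
        assert a.frac_expressing == pytest.approx(2 / 3)
        assert a.mean_log_expr == pytest.approx((0 + 2 + 3) / 3)
        b = st[st.subtype == "b"].iloc[0]
        assert b.frac_expressing == 1.0 and b.mean_log_expr == pytest.approx(1.0)

    def test_all_zero(self):
        m, lab = two_group_matrix(np.zeros((3, 1)), np.zeros((2, 1)))
        st = dotplot_stats(m, lab, ["G0"])
        assert (st.frac_expressing == 0).all() and (st.mean_log_expr == 0).all()

    def test_unknown_gene_reported_not_fatal(self, rng):
        m, lab = two_group_matrix(rng.uniform(0, 5, (3, 2)), rng.uniform(0, 5, (2, 2)))
        st = dotplot_stats(m, lab, ["G0", "Nope"])
        assert st.attrs["missing"] == ["Nope"]

    def test_scale_invariance_under_retpm(self, kept_atlas):
        lab = kept_atlas.obs.truth_label
        genes = list(kept_atlas.var_names[:5])
        st1 = dotplot_stats(kept_atlas, lab, genes)
        scaled = kept_atlas.copy()
        X = np.asarray(scaled.X) * 7.3
        scaled.X = X / X.sum(axis=1, keepdims=True) * 1e6
        st2 = dotplot_stats(scaled, lab, genes)
        assert np.allclose(st1.frac_expressing, st2.frac_expressing)
        assert np.allclose(st1.mean_log_expr, st2.mean_log_expr, atol=1e-9)

    def test_prevalence_strict_majority(self):
        xa = np.zeros((10, 2))
        xa[:6, 0] = 5.0  # 6/10 expressing
        xa[:5, 1] = 5.0  # exactly half
        m, lab = two_group_matrix(xa, np.zeros((4, 2)))
        assert prevalence_screen(m, lab, ["G0", "G1"]) == ["G0"]
        assert prevalence_screen(m, lab, []) == []


class TestAnnotation:
    def test_lineage_and_fiber_recovered_from_truth(self, kept_atlas):
        lab = kept_atlas.obs.truth_label
        lab = lab[lab != "PSN-H"]
        ann = annotate_subtypes(kept_atlas[lab.index], lab, fiber_cutpoints=(2.0, 5.5))
        crest = set(ann.index[ann.lineage == "crest"])
        assert crest == {"PSN1", "PSN9"}
        assert set(ann.index[ann.fiber == "Aβ-like"]) == {"PSN6", "PSN7", "PSN9"}
        assert ann.loc["PSN8", "fiber"] == "Aδ-like"
        assert (ann.loc[["PSN1", "PSN2", "PSN3", "PSN4", "PSN5"], "fiber"] == "C-like").all()

    def test_zero_nefh_is_c_like(self):
        m, lab = two_group_matrix(np.zeros((5, 2)), np.ones((5, 2)) * 40)
        m.var_names = ["Nefh", "Phox2b"]
        ann = annotate_subtypes(m, lab, fiber_cutpoints=(1.0, 3.0))
        assert ann.loc["a", "fiber"] == "C-like"
        assert ann.loc["a", "lineage"] == "crest"
        assert ann.loc["b", "lineage"] == "placode"

    def test_absent_gene_is_error(self, kept_atlas):
        with pytest.raises(InputError):
            annotate_subtypes(kept_atlas, kept_atlas.obs.truth_label, nefh_gene="NotHere")


class TestAbundance:
    def test_equal_counts(self):
        out = scale_abundance({"a": 1, "b": 1})
        assert list(out.scaled_count) == [200.0, 200.0]

    def test_proportional(self):
        out = scale_abundance({"a": 10, "b": 30})
        assert list(out.scaled_count) == [100.0, 300.0]
        assert out.proportion.sum() == pytest.approx(1.0)

    def test_raw_total_preserved_when_overcomplete(self):
        out = scale_abundance({"a": 0.55, "b": 0.50})  # independent estimates, 105%
        assert out.attrs["raw_total"] == pytest.approx(1.05)
        assert out.scaled_count.sum() == pytest.approx(400.0)

    def test_all_zero_is_error(self):
        with pytest.raises(InputError):
            scale_abundance({"a": 0.0})


class TestLigandReceptor:
    def _tables(self):
        psn = pd.DataFrame(
            [
                {"gene": "Lig1", "subtype": "s1", "frac_expressing": 0.8},
                {"gene": "Rec2", "subtype": "s2", "frac_expressing": 0.7},
                {"gene": "Lig3", "subtype": "s1", "frac_expressing": 0.2},
            ]
        )
        immune = pd.DataFrame(
            [
                {"gene": "Rec1", "cell_type": "mac", "frac_expressing": 0.6},
                {"gene": "Lig2", "cell_type": "tcell", "frac_expressing": 0.9},
            ]
        )
        return psn, immune

    def test_forward_and_reverse_pairs(self):
        psn, immune = self._tables()
        pairing = pd.DataFrame(
            [{"ligand": "Lig1", "receptor": "Rec1"}, {"ligand": "Lig2", "receptor": "Rec2"}]
        )
        pairs, warn = pair_ligand_receptor(psn, immune, pairing)
        dirs = sorted(p.direction for p in pairs)
        assert dirs == ["immune→psn", "psn→immune"]
        assert not warn

    def test_three_planted_bidirectional_pairs(self):
        rows_p, rows_i, rows_map = [], [], []
        for k in range(3):
            rows_p += [
                {"gene": f"L{k}", "subtype": "s1", "frac_expressing": 0.9},
                {"gene": f"R{k}", "subtype": "s2", "frac_expressing": 0.8},
            ]
            rows_i += [
                {"gene": f"R{k}", "cell_type": "mac", "frac_expressing": 0.7},
                {"gene": f"L{k}", "cell_type": "mac", "frac_expressing": 0.7},
            ]
            rows_map.append({"ligand": f"L{k}", "receptor": f"R{k}"})
        pairs, _ = pair_ligand_receptor(
            pd.DataFrame(rows_p), pd.DataFrame(rows_i), pd.DataFrame(rows_map)
        )
        assert sum(p.direction == "psn→immune" for p in pairs) == 3
        assert sum(p.direction == "immune→psn" for p in pairs) == 3

    def test_empty_immune_table_no_pairs(self):
        psn, _ = self._tables()
        immune = pd.DataFrame(columns=["gene", "cell_type", "frac_expressing"])
        pairing = pd.DataFrame([{"ligand": "Lig1", "receptor": "Rec1"}])
        pairs, _ = pair_ligand_receptor(psn, immune, pairing)
        assert pairs == []

    def test_unknown_genes_warned(self):
        psn, immune = self._tables()
        pairing = pd.DataFrame([{"ligand": "Ghost", "receptor": "Phantom"}])
        pairs, warn = pair_ligand_receptor(psn, immune, pairing)
        assert pairs == [] and len(warn) == 1
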