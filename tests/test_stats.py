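import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from divshift.stats import (
    ClassOrdering,
    binomial_tail,
    fit_slopes,
    order_classes,
    run_divshift,
    sign_enrichment,
)

from conftest import random_profile


def profile_from_positions(positions):
    """2-taxon profile whose class columns sit at given 1-D positions."""
    cols = {}
    for cls, x in positions.items():
        cols[cls] = [x, 10.0 - x]
    prof = pd.DataFrame(cols, index=["t_up", "t_down"])
    return prof.div(prof.sum(axis=0), axis=1)


class TestOrderClasses:
    def test_nested_distances_give_canonical_order(self):
        # d(L,C) < d({L,C},H) < d({L,C,H},S)
        prof = profile_from_positions({"L": 0.0, "C": 1.0, "H": 3.0, "S": 7.0})
        assert order_classes(prof).order == ["L", "C", "H", "S"]

    def test_two_classes_trivial(self):
        prof = profile_from_positions({"L": 0.0, "H": 1.0})
        assert order_classes(prof).order == ["L", "H"]

    def test_matches_exhaustive_tree_constrained_oracle(self, rng):
        """Chosen order minimizes adjacent distances over all orders the
        merge tree admits that start with the tightest pair."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist, squareform

        for _ in range(25):
            prof = random_profile(rng, n_taxa=5)
            ordering = order_classes(prof)
            cols = list(prof.columns)
            X = prof.T.to_numpy()
            D = squareform(pdist(X))
            Z = linkage(pdist(X), method="average")
            first_pair = {cols[int(Z[0, 0])], cols[int(Z[0, 1])]}

            # a permutation is tree-consistent iff every merge cluster is
            # a contiguous block
            clusters, members = [], {i: {i} for i in range(len(cols))}
            for i, row in enumerate(Z):
                merged = members[int(row[0])] | members[int(row[1])]
                members[len(cols) + i] = merged
                clusters.append({cols[j] for j in merged})

            def consistent(perm):
                for cl in clusters:
                    pos = sorted(perm.index(c) for c in cl)
                    if pos[-1] - pos[0] != len(cl) - 1:
                        return False
                return True

            def cost(perm):
                idx = [cols.index(c) for c in perm]
                return sum(D[idx[i], idx[i + 1]] for i in range(len(idx) - 1))

            best = min(
                (
                    p
                    for p in itertools.permutations(cols)
                    if consistent(list(p)) and {p[0], p[1]} == first_pair
                ),
                key=lambda p: (cost(list(p)), p),
            )
            assert tuple(ordering.order) == best

    def test_identical_columns_warn_but_are_deterministic(self):
        prof = pd.DataFrame(
            {c: [0.5, 0.5] for c in ("L", "C", "H", "S")}, index=["a", "b"]
        )
        with pytest.warns(UserWarning, match="identical"):
            o1 = order_classes(prof)
        with pytest.warns(UserWarning):
            o2 = order_classes(prof)
        assert o1.order == o2.order

    def test_newick_roundtrip_labels(self):
        prof = profile_from_positions({"L": 0.0, "C": 1.0, "H": 3.0, "S": 7.0})
        nwk = order_classes(prof).to_newick()
        assert nwk.endswith(";")
        for cls in "LCHS":
            assert cls in nwk


class TestFitSlopes:
    ordering = ClassOrdering(order=["L", "C", "H", "S"], provenance="forced")

    def frame(self, rows):
        return pd.DataFrame(rows, columns=["L", "C", "H", "S"])

    def test_exact_arithmetic(self):
        prof = self.frame([[0.4, 0.3, 0.2, 0.1]])
        out = fit_slopes(prof, self.ordering)
        assert out["slope"].iloc[0] == pytest.approx(-0.1)
        assert out["sign"].iloc[0] == "neg"

    def test_constant_is_zero_sign(self):
        out = fit_slopes(self.frame([[0.25] * 4]), self.ordering)
        assert out["sign"].iloc[0] == "zero"

    def test_hand_ols(self):
        # cov(x, y) = 2.875, var(x) = 1.25 -> slope 2.3
        out = fit_slopes(self.frame([[1.0, 2.0, 4.0, 8.0]]), self.ordering)
        assert out["slope"].iloc[0] == pytest.approx(2.3)

    def test_sign_invariant_to_affine_recoding(self, rng):
        """OLS slope sign only depends on the rank order of classes."""
        prof = random_profile(rng, n_taxa=8)
        ordering = ClassOrdering(order=list(prof.columns), provenance="forced")
        base = fit_slopes(prof, ordering)
        Y = prof[ordering.order].to_numpy()
        for a, b in [(2.0, 3.0), (-1.0, 0.5), (100.0, 10.0)]:
            x = a + b * np.arange(Y.shape[1])
            xc = x - x.mean()
            slopes = (Y - Y.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
            assert (np.sign(slopes) == np.sign(base["slope"].to_numpy())).all()

    def test_reversed_ordering_negates_slopes(self, rng):
        prof = random_profile(rng)
        ordering = ClassOrdering(order=list(prof.columns), provenance="forced")
        fwd = fit_slopes(prof, ordering)["slope"]
        rev = fit_slopes(prof, ordering.reversed())["slope"]
        np.testing.assert_allclose(fwd, -rev)


class TestSignEnrichment:
    def frame(self, n_neg, n_pos, n_zero=0):
        signs = ["neg"] * n_neg + ["pos"] * n_pos + ["zero"] * n_zero
        return pd.DataFrame({"slope": 0.0, "sign": signs},
                            index=[f"t{i}" for i in range(len(signs))])

    def test_headline_19_of_25(self):
        res = sign_enrichment(self.frame(19, 6))
        assert res.k == 19 and res.n == 25
        assert res.p_value == pytest.approx(0.0073166, rel=1e-4)

    def test_forced_order_22_of_25(self):
        res = sign_enrichment(self.frame(22, 3))
        assert res.p_value == pytest.approx(2626 / 2**25)

    def test_zero_negatives_is_full_tail(self):
        assert sign_enrichment(self.frame(0, 7)).p_value == 1.0

    def test_zero_slopes_excluded_and_counted(self):
        res = sign_enrichment(self.frame(3, 1, n_zero=2))
        assert (res.k, res.n, res.n_zero) == (3, 4, 2)

    def test_all_zero_slopes_error(self):
        with pytest.raises(ValueError, match="no informative slopes"):
            sign_enrichment(self.frame(0, 0, n_zero=4))

    @given(n=st.integers(1, 25), k_frac=st.floats(0, 1))
    def test_matches_exact_integer_oracle(self, n, k_frac):
        """Tail equals sum_{i>=k} C(n,i) / 2^n by direct rational summation."""
        k = int(round(k_frac * n))
        expected = Fraction(sum(comb(n, i) for i in range(k, n + 1)), 2**n)
        assert binomial_tail(k, n) == pytest.approx(float(expected), rel=1e-15)

    def test_two_sided_doubles_smaller_tail(self):
        res = sign_enrichment(self.frame(19, 6), alternative="two-sided")
        assert res.p_value == pytest.approx(2 * binomial_tail(19, 25))


class TestRunDivshift:
    def test_forced_equals_clustered_when_identical(self, rng):
        prof = random_profile(rng)
        rep = run_divshift(prof)
        forced = run_divshift(prof, forced_order=rep.ordering.order)
        assert forced.ordering.order == rep.ordering.order
        pd.testing.assert_frame_equal(forced.slopes, rep.slopes)
        assert forced.enrichment.p_value == rep.enrichment.p_value

    def test_two_taxa_monotone_up_down(self):
        prof = pd.DataFrame(
            {"L": [0.1, 0.9], "C": [0.2, 0.8], "H": [0.3, 0.7], "S": [0.4, 0.6]},
            index=["up", "down"],
        )
        rep = run_divshift(prof, forced_order=["L", "C", "H", "S"])
        res = rep.enrichment
        assert (res.k, res.n) == (1, 2)
        assert res.p_value == pytest.approx(0.75)

    def test_reversal_maps_k_to_n_minus_k(self, rng):
        prof = random_profile(rng, n_taxa=12)
        rep = run_divshift(prof)
        rev = run_divshift(prof, forced_order=list(reversed(rep.ordering.order)))
        assert rev.enrichment.k == rep.enrichment.n - rep.enrichment.k

    def test_bad_forced_order_rejected(self, rng):
        prof = random_profile(rng)
        with pytest.raises(ValueError, match="permutation"):
            run_divshift(prof, forced_order=["L", "C", "H", "H"])
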