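import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from divshift.community import AbundanceTable, normalize_abundance
from divshift.functional import (
    build_pathway_profile,
    call_pathways,
    compare_nutrient_processes,
    fisher_exact_2x2,
    functional_divshift,
    include_genomes_per_site,
    minpath_infer,
)


def props_table(rows, samples):
    df = pd.DataFrame(rows, columns=samples)
    return AbundanceTable(df.div(df.sum(axis=0), axis=1), mode="proportions")


class TestInclusionCutoff:
    def test_max_scaled_worked_example(self):
        # -log10 of (0.10, 0.09, 0.01)/0.10 = (0, 0.046, 1.0)
        t = AbundanceTable(
            pd.DataFrame({"s1": [0.10, 0.90], "s2": [0.09, 0.91], "s3": [0.01, 0.99]},
                         index=["g", "filler"]),
            mode="proportions",
        )
        inc = include_genomes_per_site(t, cutoff=0.25)
        assert "g" in inc["s1"] and "g" in inc["s2"] and "g" not in inc["s3"]

    def test_cutoff_zero_keeps_only_the_maximum(self):
        t = AbundanceTable(
            pd.DataFrame({"s1": [0.2, 0.8], "s2": [0.1, 0.9]}, index=["g", "o"]),
            mode="proportions",
        )
        inc = include_genomes_per_site(t, cutoff=0.0)
        assert "g" in inc["s1"] and "g" not in inc["s2"]

    def test_infinite_cutoff_keeps_everything_nonzero(self):
        t = AbundanceTable(
            pd.DataFrame({"s1": [0.0, 1.0], "s2": [0.5, 0.5]}, index=["g", "o"]),
            mode="proportions",
        )
        inc = include_genomes_per_site(t, cutoff=np.inf)
        assert "g" not in inc["s1"] and "g" in inc["s2"]

    def test_negative_cutoff_rejected(self):
        t = props_table([[1.0]], ["s1"])
        with pytest.raises(ValueError, match="cutoff"):
            include_genomes_per_site(t, cutoff=-0.1)

    def test_raw_transform_is_stricter(self):
        t = AbundanceTable(
            pd.DataFrame({"s1": [0.6, 0.4], "s2": [0.4, 0.6]}, index=["g", "o"]),
            mode="proportions",
        )
        raw = include_genomes_per_site(t, cutoff=0.25, transform="raw")
        # only abundances above 10**-0.25 ~ 0.56 survive the raw reading
        assert raw["s1"] == {"g"} and raw["s2"] == {"o"}


class TestMinPath:
    defs = {"P1": {"e1"}, "P2": {"e2"}, "P3": {"e1", "e2"}}

    def test_single_pathway_beats_two(self):
        assert minpath_infer({"e1", "e2"}, self.defs).pathways == {"P3"}

    def test_empty_enzymes_empty_pathways(self):
        assert minpath_infer(set(), self.defs).pathways == frozenset()

    def test_single_hit_flagged(self):
        res = minpath_infer({"e1"}, {"P1": {"e1", "e2", "e3"}})
        assert res.pathways == {"P1"} and res.single_hit == {"P1"}

    def test_unmapped_enzymes_warned(self):
        with pytest.warns(UserWarning, match="not in any pathway"):
            res = minpath_infer({"e1", "zz"}, self.defs)
        assert res.unmapped == {"zz"}

    def test_empty_definitions_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            minpath_infer({"e1"}, {})

    def test_exact_matches_exhaustive_search(self, rng):
        """Branch-and-bound equals brute-force minimum cover, <= 12 pathways."""
        for _ in range(60):
            n_pw = rng.integers(2, 13)
            universe = [f"e{i}" for i in range(rng.integers(3, 12))]
            defs = {
                f"P{j}": set(rng.choice(universe,
                                        size=rng.integers(1, len(universe) + 1),
                                        replace=False))
                for j in range(n_pw)
            }
            observed = set(rng.choice(universe,
                                      size=rng.integers(1, len(universe) + 1),
                                      replace=False))
            coverable = observed & set().union(*defs.values())
            got = minpath_infer(observed, defs).pathways
            assert coverable <= set().union(*(defs[p] for p in got)) if got else not coverable
            best = None
            for size in range(0, n_pw + 1):
                for combo in itertools.combinations(sorted(defs), size):
                    if coverable <= set().union(set(), *(defs[p] for p in combo)):
                        best = size
                        break
                if best is not None:
                    break
            assert len(got) == best

    def test_greedy_covers_everything_coverable(self, rng):
        for _ in range(100):
            universe = [f"e{i}" for i in range(30)]
            defs = {
                f"P{j}": set(rng.choice(universe, size=rng.integers(2, 8),
                                        replace=False))
                for j in range(40)  # > exact limit -> greedy path
            }
            observed = set(rng.choice(universe, size=15, replace=False))
            res = minpath_infer(observed, defs)
            coverable = observed & set().union(*defs.values())
            covered = set().union(set(), *(defs[p] & observed for p in res.pathways))
            assert covered == coverable


class TestPathwayProfile:
    taxonomy = pd.DataFrame(
        {"phylum": ["P1", "P2"], "class": ["", ""]}, index=["g1", "g2"]
    )
    design = pd.Series({"s1": "L", "s2": "H"})

    def test_two_pathways_split_evenly(self):
        prof = build_pathway_profile(
            {"s1": {"g1"}, "s2": {"g1"}},
            {"g1": {"pwA", "pwB"}},
            self.taxonomy,
            self.design,
            split_proteobacteria_by_class=False,
        )
        np.testing.assert_allclose(prof.to_numpy(), 0.5)
        assert set(prof.index) == {("P1", "pwA"), ("P1", "pwB")}

    def test_duplicate_annotations_do_not_inflate(self):
        a = build_pathway_profile(
            {"s1": {"g1"}, "s2": {"g1"}},
            {"g1": ["pwA", "pwA", "pwB"]},
            self.taxonomy,
            self.design,
            split_proteobacteria_by_class=False,
        )
        np.testing.assert_allclose(a.to_numpy(), 0.5)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="H"):
            build_pathway_profile(
                {"s1": {"g1"}, "s2": set()},
                {"g1": {"pwA"}},
                self.taxonomy,
                self.design,
                split_proteobacteria_by_class=False,
            )

    def test_oxidative_share_lower_in_H(self, small_tilted_dataset, as_bundle):
        """The injected oxidative loss shows up in the class profile."""
        ds = small_tilted_dataset
        props = normalize_abundance(ds.counts)
        included = include_genomes_per_site(props)
        prof = build_pathway_profile(
            included, ds.annotations, ds.taxonomy, ds.design,
            split_proteobacteria_by_class=False,
        )
        ox = set(ds.truth.oxidative_functions)
        is_ox = prof.index.get_level_values("feature").isin(ox)
        assert prof.loc[is_ox, "H"].sum() < prof.loc[is_ox, "L"].sum()


class TestFunctionalDivshift:
    def test_reversed_order_maps_k(self, small_tilted_dataset):
        ds = small_tilted_dataset
        props = normalize_abundance(ds.counts)
        included = include_genomes_per_site(props)
        calls = call_pathways(ds.annotations, ds.pathways)
        prof = build_pathway_profile(included, calls, ds.taxonomy, ds.design)
        fwd = functional_divshift(prof, forced_order=["L", "C", "H", "S"])
        rev = functional_divshift(prof, forced_order=["S", "H", "C", "L"])
        assert rev.enrichment.k == fwd.enrichment.n - fwd.enrichment.k

    def test_flat_profile_has_no_informative_slopes(self):
        prof = pd.DataFrame(
            {c: [0.5, 0.5] for c in ("L", "C", "H", "S")},
            index=pd.MultiIndex.from_tuples(
                [("P1", "pwA"), ("P1", "pwB")], names=["taxon", "feature"]
            ),
        )
        with pytest.raises(ValueError, match="no informative slopes"):
            functional_divshift(prof, forced_order=["L", "C", "H", "S"])


def enumerate_fisher(table):
    """Independent oracle: exact rational enumeration over fixed margins."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    probs = {}
    for x in range(max(0, c1 - (c + d)), min(r1, c1) + 1):
        probs[x] = Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisher:
    def test_worked_case(self):
        assert fisher_exact_2x2([[0, 5], [5, 0]]) == pytest.approx(2 / 252)

    def test_identical_rows_p_one(self):
        assert fisher_exact_2x2([[3, 2], [3, 2]]) == pytest.approx(1.0)

    def test_matches_enumeration_and_scipy(self, rng):
        for _ in range(200):
            t = rng.integers(0, 12, size=(2, 2))
            p = fisher_exact_2x2(t)
            assert p == pytest.approx(enumerate_fisher(t), rel=1e-9)
            assert p == pytest.approx(scipy_fisher(t).pvalue, rel=1e-7)


class TestNutrientProcesses:
    def separated_presence(self):
        """Two groups of sites with disjoint functional repertoires."""
        funcs = [f"f{i}" for i in range(30)]
        rows = {}
        for s in ("A1", "A2", "A3"):
            rows[s] = [1] * 15 + [0] * 15
        for s in ("B1", "B2", "B3"):
            rows[s] = [0] * 15 + [1] * 15
        presence = pd.DataFrame.from_dict(rows, orient="index", columns=funcs)
        # processes aligned with the blocks: group A carries all carbon
        # oxidation, group B all sulfur reduction
        pmap = pd.Series(
            {f: ("carbon_oxidation" if i < 15 else "sulfur_reduction")
             for i, f in enumerate(funcs)}
        )
        design = pd.Series({"A1": "L", "A2": "L", "A3": "L",
                            "B1": "H", "B2": "H", "B3": "H"})
        return presence, pmap, design

    def test_separated_groups_fully_supported(self):
        presence, pmap, design = self.separated_presence()
        rep = compare_nutrient_processes(presence, pmap, design, n_boot=500, seed=1)
        top = rep.clades[rep.clades["size"] == 3]
        assert len(top) == 2
        assert (top["bp"] > 0.95).all()
        # saturated (flat) curves carry no curvature: AU agrees with BP
        flat = top[top["bp"] == 1.0]
        assert len(flat) >= 1
        assert (np.abs(flat["au"] - flat["bp"]) < 0.05).all()
        assert ((top["au"] > 0.5) & (top["au"] <= 1.0)).all()

    def test_fisher_block_contrasts_transects(self):
        presence, pmap, design = self.separated_presence()
        rep = compare_nutrient_processes(presence, pmap, design, n_boot=50, seed=1)
        # 15 functions per process, completely disjoint between transects
        assert (rep.fisher["p_value"] < 0.05).all()

    def test_unmapped_function_rejected(self):
        presence, pmap, design = self.separated_presence()
        with pytest.raises(ValueError, match="f0"):
            compare_nutrient_processes(presence, pmap.drop("f0"), design, n_boot=10)
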