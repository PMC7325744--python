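import numpy as np
import pytest

from popdiallel.datamodel_io import TraitSpec, default_trait_specs
from popdiallel.errors import (
    DegenerateTraitError,
    EmptyDesignError,
    IntegrityError,
)
from popdiallel.ranking_index import (
    TraitSummary,
    orient_traits,
    rank_from_fieldbook,
    rank_hybrids,
    rank_table,
    summarize_traits,
    trait_term,
)


def specs(**weights):
    """TraitSpecs for ad-hoc trait names, all maximize unless noted."""
    out = []
    for name, w in weights.items():
        orientation = "complement_then_maximize" if name == "rot" else "maximize"
        out.append(TraitSpec(name=name, orientation=orientation, weight=w))
    return out


def summary(hybrid, trait, mean, sd=1.0, n=6):
    return TraitSummary(hybrid=hybrid, trait=trait, mean=mean, sd=sd, n=n)


class TestOrientTraits:
    def test_rot_complemented(self):
        (oriented,) = orient_traits(
            [summary("H1", "rot", 0.25)], specs(rot=0.5)
        )
        assert oriented.mean == pytest.approx(0.75)
        assert oriented.sd == 1.0  # sd unchanged

    def test_rot_zero_maps_to_one(self):
        (oriented,) = orient_traits([summary("H1", "rot", 0.0)], specs(rot=0.5))
        assert oriented.mean == pytest.approx(1.0)

    def test_maximize_identity(self):
        (oriented,) = orient_traits([summary("H1", "el", 18.0)], specs(el=0.5))
        assert oriented.mean == 18.0

    def test_excluded_dropped(self):
        sp = [TraitSpec(name="dap", orientation="excluded", weight=0.0)]
        assert orient_traits([summary("H1", "dap", 60.0)], sp) == []

    def test_complement_requires_proportion(self):
        sp = [
            TraitSpec(
                name="el", orientation="complement_then_maximize", weight=0.5
            )
        ]
        with pytest.raises(IntegrityError):
            orient_traits([summary("H1", "el", 18.0)], sp)


class TestTraitTerm:
    def test_at_maximum_is_zero(self):
        assert trait_term(10.0, 10.0, sd=3.0, sd_max=3.0, weight=0.85) == 0.0

    def test_hand_value(self):
        # (8/10 - 1)^2 * 0.85 * (1/2) = 0.04 * 0.85 * 0.5 = 0.017
        assert trait_term(8.0, 10.0, sd=1.0, sd_max=2.0, weight=0.85) == (
            pytest.approx(0.017)
        )

    def test_zero_weight_contributes_nothing(self):
        assert trait_term(3.0, 10.0, sd=1.0, sd_max=2.0, weight=0.0) == 0.0

    def test_zero_best_value_degenerate(self):
        with pytest.raises(DegenerateTraitError):
            trait_term(0.0, 0.0, sd=1.0, sd_max=1.0, weight=0.5)

    def test_divisive_variant(self):
        mult = trait_term(8.0, 10.0, 1.0, 2.0, 0.85, variant="multiplicative")
        div = trait_term(8.0, 10.0, 1.0, 2.0, 0.85, variant="divisive")
        assert div == pytest.approx(mult * 4.0)  # (2/1) vs (1/2)


class TestRankHybrids:
    def toy_summaries(self):
        # three hybrids, two weighted traits
        return [
            summary("H1", "el", 20.0, sd=2.0),
            summary("H1", "ev", 800.0, sd=40.0),
            summary("H2", "el", 16.0, sd=1.0),
            summary("H2", "ev", 760.0, sd=20.0),
            summary("H3", "el", 18.0, sd=2.0),
            summary("H3", "ev", 700.0, sd=40.0),
        ]

    def toy_specs(self):
        return specs(el=0.5, ev=0.85)

    def hand_oracle(self):
        # direct evaluation of the index formula per hybrid
        el_max, ev_max, el_sdmax, ev_sdmax = 20.0, 800.0, 2.0, 40.0
        totals = {}
        for h, el, el_sd, ev, ev_sd in [
            ("H1", 20.0, 2.0, 800.0, 40.0),
            ("H2", 16.0, 1.0, 760.0, 20.0),
            ("H3", 18.0, 2.0, 700.0, 40.0),
        ]:
            totals[h] = (el / el_max - 1) ** 2 * 0.5 * (el_sd / el_sdmax) + (
                ev / ev_max - 1
            ) ** 2 * 0.85 * (ev_sd / ev_sdmax)
        return totals

    def test_best_hybrid_scores_zero(self):
        results = rank_hybrids(self.toy_summaries(), self.toy_specs())
        best = results[0]
        assert best.hybrid == "H1"
        assert best.total == 0.0
        assert best.rank == 1

    def test_totals_match_hand_oracle(self):
        results = rank_hybrids(self.toy_summaries(), self.toy_specs())
        oracle = self.hand_oracle()
        for r in results:
            assert r.total == pytest.approx(oracle[r.hybrid], abs=1e-12)
        totals = [r.total for r in results]
        assert totals == sorted(totals)

    def test_smaller_total_listed_first(self):
        results = rank_hybrids(
            [
                summary("Hgood", "el", 19.0, sd=1.0),
                summary("Hbad", "el", 10.0, sd=1.0),
                summary("Hbest", "el", 20.0, sd=1.0),
            ],
            specs(el=0.5),
        )
        assert [r.hybrid for r in results] == ["Hbest", "Hgood", "Hbad"]

    def test_decomposition_reproduces_total(self):
        for r in rank_hybrids(self.toy_summaries(), self.toy_specs()):
            assert sum(r.contributions.values()) == pytest.approx(
                r.total, abs=1e-12
            )
            assert all(c >= 0 for c in r.contributions.values())

    def test_scale_invariance(self):
        results = rank_hybrids(self.toy_summaries(), self.toy_specs())
        scaled = [
            TraitSummary(
                hybrid=s.hybrid,
                trait=s.trait,
                mean=s.mean * (3.7 if s.trait == "el" else 1.0),
                sd=s.sd * (3.7 if s.trait == "el" else 1.0),
                n=s.n,
            )
            for s in self.toy_summaries()
        ]
        rescaled = rank_hybrids(scaled, self.toy_specs())
        for a, b in zip(results, rescaled):
            assert a.hybrid == b.hybrid
            assert a.total == pytest.approx(b.total, abs=1e-12)

    def test_zero_weight_trait_changes_nothing(self):
        base = rank_hybrids(self.toy_summaries(), self.toy_specs())
        extra = self.toy_summaries() + [
            summary("H1", "dap", 60.0),
            summary("H2", "dap", 58.0),
            summary("H3", "dap", 65.0),
        ]
        spec_extra = self.toy_specs() + [
            TraitSpec(name="dap", orientation="excluded", weight=0.0)
        ]
        with_extra = rank_hybrids(extra, spec_extra)
        for a, b in zip(base, with_extra):
            assert a.total == pytest.approx(b.total, abs=1e-15)

    def test_improving_mean_never_hurts(self):
        base = rank_hybrids(self.toy_summaries(), self.toy_specs())
        h2_base = next(r for r in base if r.hybrid == "H2")
        improved = [
            TraitSummary(
                hybrid=s.hybrid,
                trait=s.trait,
                mean=18.0 if (s.hybrid, s.trait) == ("H2", "el") else s.mean,
                sd=s.sd,
                n=s.n,
            )
            for s in self.toy_summaries()
        ]
        h2_new = next(
            r for r in rank_hybrids(improved, self.toy_specs())
            if r.hybrid == "H2"
        )
        assert h2_new.total <= h2_base.total

    def test_missing_trait_imputed_pessimistically(self):
        partial = [s for s in self.toy_summaries() if not (
            s.hybrid == "H3" and s.trait == "ev"
        )]
        results = rank_hybrids(partial, self.toy_specs())
        h3 = next(r for r in results if r.hybrid == "H3")
        assert h3.imputed_traits == ["ev"]
        worst_ev = max(
            r.contributions["ev"] for r in results if r.hybrid != "H3"
        )
        assert h3.contributions["ev"] == pytest.approx(worst_ev)

    def test_zero_hybrids_rejected(self):
        with pytest.raises(EmptyDesignError):
            rank_hybrids([], self.toy_specs())

    def test_ties_share_rank(self):
        results = rank_hybrids(
            [
                summary("H1", "el", 18.0, sd=1.0),
                summary("H2", "el", 18.0, sd=1.0),
                summary("H3", "el", 20.0, sd=1.0),
            ],
            specs(el=0.5),
        )
        ranks = {r.hybrid: r.rank for r in results}
        assert ranks["H3"] == 1
        assert ranks["H1"] == ranks["H2"] == 2


class TestFieldbookPipeline:
    def test_end_to_end_rank(self, default_trial):
        plots, _ = default_trial
        results = rank_from_fieldbook(plots)
        assert len(results) == 44
        # ten weighted traits in the default configuration
        assert all(len(r.contributions) == 10 for r in results)
        table = rank_table(results)
        assert list(table.columns[:3]) == ["hybrid", "total", "rank"]
        assert table["total"].is_monotonic_increasing

    def test_summaries_pool_locations(self, default_trial):
        plots, _ = default_trial
        summaries = summarize_traits(plots)
        el = [s for s in summaries if s.trait == "el"]
        assert all(s.n == 12 for s in el)  # 2 locations x 6 rows

    def test_default_specs_rank_ten_traits(self):
        weighted = [
            s for s in default_trait_specs() if s.weight > 0
        ]
        assert len(weighted) == 10
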