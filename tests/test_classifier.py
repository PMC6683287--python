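import itertools

import pytest

from phageome.classify import (
    CLASS_BACTERIA,
    CLASS_CONTAMINATION,
    CLASS_NA,
    CLASS_PHAGE,
    CLASS_PUTATIVE,
    DEFAULT_PRECEDENCE,
    BestHit,
    EvidenceBundle,
    LifestyleEvidence,
    assign_family,
    assign_host,
    assign_lifestyle,
    audit_conflicts,
    classify_contig,
    evidence_flags,
    filter_contigs,
)
from phageome.calibration import cutoff_for_size
from phageome.wgrr import InputError

from conftest import make_repertoire, toy_curve


def bundle(contig_id="c1", n=10, **kwargs):
    return EvidenceBundle(contig_id=contig_id, n_proteins=n, **kwargs)


def phage_hit(wgrr, family="Siphoviridae", lifestyle="temperate",
              host="Firmicutes", db="phage_ref"):
    return {db: BestHit("ref1", wgrr, family, lifestyle, host)}


class TestFilterContigs:
    def test_default_threshold_keeps_three_or_more_orfs(self):
        contigs = [make_repertoire(f"c{n}", n) for n in (1, 2, 3, 4)]
        kept = filter_contigs(contigs)
        assert [c.element_id for c in kept] == ["c3", "c4"]

    def test_empty_input(self):
        assert filter_contigs([]) == []

    def test_min_orfs_one_is_identity(self):
        contigs = [make_repertoire(f"c{n}", n) for n in (1, 2, 3)]
        assert filter_contigs(contigs, min_orfs=1) == contigs

    def test_invalid_threshold(self):
        with pytest.raises(InputError):
            filter_contigs([], min_orfs=0)


class TestAssignFamily:
    def test_above_cutoff_assigns_best_hit_family(self, curves):
        ev = bundle(n=10, best_wgrr_hits=phage_hit(40.0))
        assert assign_family(ev, curves) == "Siphoviridae"

    def test_below_cutoff_assigns_nothing(self, curves):
        cutoff = cutoff_for_size(curves[("phage_ref", "family")], 10)
        ev = bundle(n=10, best_wgrr_hits=phage_hit(cutoff - 1.0))
        assert assign_family(ev, curves) is None

    def test_prophage_databases_never_give_family(self, curves):
        curves = dict(curves)
        curves[("prophage_complete", "family")] = toy_curve(
            "family", database="prophage_complete")
        ev = bundle(n=10, best_wgrr_hits=phage_hit(99.0, db="prophage_complete"))
        assert assign_family(ev, curves) is None

    def test_monotone_in_wgrr(self, curves):
        assigned_from = None
        for wgrr in range(0, 101, 5):
            ev = bundle(n=10, best_wgrr_hits=phage_hit(float(wgrr)))
            if assign_family(ev, curves) is not None and assigned_from is None:
                assigned_from = wgrr
            if assigned_from is not None:
                assert assign_family(ev, curves) == "Siphoviridae"


class TestAssignLifestyle:
    def test_confident_when_two_sd_apart(self, curves):
        ev = bundle(n=25, lifestyle_probs=LifestyleEvidence(0.8, 0.2, 0.05))
        assert assign_lifestyle(ev, curves) == "virulent_confident"

    def test_nonconfident_when_means_close(self, curves):
        ev = bundle(n=25, lifestyle_probs=LifestyleEvidence(0.55, 0.45, 0.2))
        assert assign_lifestyle(ev, curves) == "virulent_nonconfident"

    def test_temperate_direction(self, curves):
        ev = bundle(n=30, lifestyle_probs=LifestyleEvidence(0.1, 0.9, 0.1))
        assert assign_lifestyle(ev, curves) == "temperate_confident"

    def test_short_contig_uses_wgrr_route(self, curves):
        ev = bundle(n=10, best_wgrr_hits=phage_hit(50.0, lifestyle="temperate"))
        assert assign_lifestyle(ev, curves) == "temperate_nonconfident"

    def test_short_contig_below_cutoff_unclassified(self, curves):
        ev = bundle(n=10, best_wgrr_hits=phage_hit(1.0, lifestyle="temperate"))
        assert assign_lifestyle(ev, curves) == "unclassified"

    def test_exactly_19_proteins_uses_wgrr_route(self, curves):
        # the replicate-probability route needs MORE than 19 proteins
        ev = bundle(n=19, best_wgrr_hits=phage_hit(50.0, lifestyle="virulent"),
                    lifestyle_probs=LifestyleEvidence(0.2, 0.8, 0.01))
        assert assign_lifestyle(ev, curves) == "virulent_nonconfident"

    def test_no_evidence_unclassified(self, curves):
        assert assign_lifestyle(bundle(n=25), curves) == "unclassified"


class TestAssignHost:
    def _curves(self, curves):
        curves = dict(curves)
        for db in ("prophage_complete", "prophage_draft"):
            curves[(db, "host_phylum")] = toy_curve("host_phylum", database=db)
        return curves

    def test_single_database_hit(self, curves):
        ev = bundle(n=10, best_wgrr_hits=phage_hit(50.0, host="Firmicutes"))
        assert assign_host(ev, self._curves(curves)) == "Firmicutes"

    def test_contradiction_between_databases(self, curves):
        hits = {
            "phage_ref": BestHit("r1", 50.0, host_phylum="Firmicutes"),
            "prophage_complete": BestHit("r2", 60.0, host_phylum="Bacteroidetes"),
        }
        ev = bundle(n=10, best_wgrr_hits=hits)
        assert assign_host(ev, self._curves(curves)) is None

    def test_agreeing_databases(self, curves):
        hits = {
            "phage_ref": BestHit("r1", 50.0, host_phylum="Firmicutes"),
            "prophage_draft": BestHit("r3", 70.0, host_phylum="Firmicutes"),
        }
        ev = bundle(n=10, best_wgrr_hits=hits)
        assert assign_host(ev, self._curves(curves)) == "Firmicutes"

    def test_below_threshold_hits_ignored(self, curves):
        ev = bundle(n=10, best_wgrr_hits=phage_hit(0.5, host="Firmicutes"))
        assert assign_host(ev, self._curves(curves)) is None

    def test_no_hits(self, curves):
        assert assign_host(bundle(), self._curves(curves)) is None


def _bundle_for_combo(cid, family, signal, bacteria, contamination):
    kwargs = {}
    if family:
        kwargs["best_wgrr_hits"] = phage_hit(90.0)
    if signal:
        kwargs["phage_signal_category"] = 2
    if bacteria:
        kwargs["bacterial_marker_hits"] = 3
    if contamination:
        kwargs["nt_hits"] = [("human", 0.95)]
    return bundle(cid, n=10, **kwargs)


class TestDecisionAlgorithm:
    def test_empty_evidence_is_na(self, curves):
        assert classify_contig(bundle(), curves).klass == CLASS_NA

    def test_phage_beats_bacterial_evidence(self, curves):
        ev = bundle(n=10, best_wgrr_hits=phage_hit(90.0),
                    bacterial_marker_hits=5, has_16s=True)
        result = classify_contig(ev, curves)
        assert result.klass == CLASS_PHAGE
        assert result.family == "Siphoviridae"

    def test_any_signal_category_gives_putative_phage(self, curves):
        for category in range(1, 7):
            ev = bundle(n=10, phage_signal_category=category)
            assert classify_contig(ev, curves).klass == CLASS_PUTATIVE

    def test_invalid_signal_category_rejected(self):
        with pytest.raises(InputError, match="outside 1-6"):
            bundle(phage_signal_category=7)

    def test_sub_coverage_contamination_is_na(self, curves):
        ev = bundle(n=10, nt_hits=[("human", 0.5)])
        assert classify_contig(ev, curves).klass == CLASS_NA

    def test_unknown_taxonomy_is_not_contamination(self, curves):
        ev = bundle(n=10, nt_hits=[("uncultured_bacterium", 0.99)])
        assert classify_contig(ev, curves).klass == CLASS_NA

    def test_family_only_for_phage_class(self, curves):
        ev = bundle(n=10, phage_signal_category=1)
        result = classify_contig(ev, curves)
        assert result.klass == CLASS_PUTATIVE
        assert result.family is None

    def test_lifestyle_and_host_filled_for_phage_classes(self, curves):
        ev = bundle(n=10, best_wgrr_hits=phage_hit(90.0))
        result = classify_contig(ev, curves)
        assert result.lifestyle == "temperate_nonconfident"
        assert result.host_phylum == "Firmicutes"
        bacteria = classify_contig(bundle(n=10, has_16s=True), curves)
        assert bacteria.lifestyle == "unclassified"
        assert bacteria.host_phylum is None

    def test_truth_table_over_all_evidence_combinations(self, curves):
        for combo in itertools.product([False, True], repeat=4):
            family, signal, bacteria, contamination = combo
            ev = _bundle_for_combo("c", *combo)
            expected = CLASS_NA
            for klass, present in zip(
                DEFAULT_PRECEDENCE, (family, signal, bacteria, contamination)
            ):
                if present:
                    expected = klass
                    break
            assert classify_contig(ev, curves).klass == expected, combo

    def test_phage_markers_optional_or_term(self, curves):
        ev = bundle(n=10, phage_marker_hits=2)
        assert classify_contig(ev, curves).klass == CLASS_NA
        assert classify_contig(ev, curves,
                               use_phage_markers=True).klass == CLASS_PUTATIVE

    def test_invalid_precedence_rejected(self, curves):
        with pytest.raises(InputError, match="permutation"):
            classify_contig(bundle(), curves, precedence=(CLASS_PHAGE,))


class TestAuditConflicts:
    def test_conflicting_bundle_flagged(self, curves):
        ev = bundle(n=10, best_wgrr_hits=phage_hit(90.0), has_16s=True)
        table = audit_conflicts([ev], curves)
        assert list(table.contig_id) == ["c1"]
        assert bool(table[CLASS_PHAGE].iloc[0])
        assert bool(table[CLASS_BACTERIA].iloc[0])

    def test_all_na_bundles_give_empty_table(self, curves):
        table = audit_conflicts([bundle(f"c{i}") for i in range(5)], curves)
        assert table.empty

    def test_single_evidence_not_flagged(self, curves):
        table = audit_conflicts([bundle(phage_signal_category=1)], curves)
        assert table.empty

    def test_precedence_changes_only_flagged_contigs(self, curves):
        bundles = [
            _bundle_for_combo(f"c{i}", *combo)
            for i, combo in enumerate(itertools.product([False, True], repeat=4))
        ]
        flagged = set(audit_conflicts(bundles, curves).contig_id)
        baseline = {
            b.contig_id: classify_contig(b, curves).klass for b in bundles
        }
        for precedence in itertools.permutations(DEFAULT_PRECEDENCE):
            for b in bundles:
                klass = classify_contig(b, curves, precedence=precedence).klass
                if klass != baseline[b.contig_id]:
                    assert b.contig_id in flagged

    def test_flags_agree_with_evidence_flags(self, curves):
        ev = _bundle_for_combo("c9", True, True, False, True)
        flags = evidence_flags(ev, curves)
        assert flags[CLASS_PHAGE] and flags[CLASS_PUTATIVE]
        assert flags[CLASS_CONTAMINATION] and not flags[CLASS_BACTERIA]
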