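"""TAIL/IDOL decomposition, overlap resolution, internal-domain loss."""

import itertools

import numpy as np
import pytest

from hijackscan.architecture import (
    architecture_string,
    decompose,
    detect_internal_loss,
    idol_length,
    resolve_overlaps,
    summarize_family,
    tail_length,
)
from hijackscan.io_model import DomainHit, Family, FamilyType, ProteinRecord, TaxonClass

from conftest import make_record


def hit(start, end, score=None, domain="D", pid="P1"):
    return DomainHit(pid, domain, start, end, score)


def oracle_resolve(hits):
    """Lexicographically best maximal compatible subset under the same order.

    Among all pairwise-compatible subsets to which no further hit can be
    added, pick the one whose sorted priority-rank tuple is smallest —
    the independent characterization of greedy retention.
    """
    def compatible(subset):
        return all(a.end < b.start or b.end < a.start
                   for a, b in itertools.combinations(subset, 2))

    from hijackscan.architecture import _hit_priority

    ranked = sorted(hits, key=_hit_priority)
    rank = {id(h): i for i, h in enumerate(ranked)}
    best = None
    for mask in range(1, 2 ** len(hits)):
        subset = [h for i, h in enumerate(hits) if mask >> i & 1]
        if not compatible(subset):
            continue
        if any(compatible(subset + [h]) for h in hits
               if id(h) not in {id(s) for s in subset}):
            continue  # not maximal
        key = tuple(sorted(rank[id(h)] for h in subset))
        if best is None or key < best[0]:
            best = (key, subset)
    return sorted(best[1], key=lambda h: h.start)


class TestResolveOverlaps:
    def test_disjoint_hits_both_retained(self):
        hits = [hit(10, 20, 5.0, "A"), hit(30, 40, 1.0, "B")]
        assert resolve_overlaps(hits) == hits

    def test_higher_score_wins_overlap(self):
        keep = hit(10, 80, 50.0, "A")
        drop = hit(70, 120, 30.0, "B")
        assert resolve_overlaps([drop, keep]) == [keep]

    def test_nested_hit_counts_as_overlap(self):
        outer = hit(10, 100, 60.0, "A")
        inner = hit(40, 50, 10.0, "B")
        assert resolve_overlaps([inner, outer]) == [outer]

    def test_score_tie_prefers_longer_then_leftmost(self):
        long_hit = hit(10, 60, 5.0, "A")
        short_hit = hit(55, 80, 5.0, "B")
        assert resolve_overlaps([short_hit, long_hit]) == [long_hit]

    def test_matches_exhaustive_maximal_subset_oracle(self, rng):
        for _ in range(150):
            n = int(rng.integers(1, 8))
            hits = []
            for j in range(n):
                start = int(rng.integers(1, 120))
                end = start + int(rng.integers(0, 50))
                score = float(rng.integers(0, 6)) if rng.random() < 0.8 else None
                hits.append(hit(start, end, score, domain=f"D{j}"))
            assert resolve_overlaps(hits) == oracle_resolve(hits)


class TestDecompose:
    def test_full_length_single_domain_has_no_linkers(self):
        rec = make_record("P1", length=100)
        d = decompose(rec, [hit(1, 100)])
        assert (d.n_tail_len, d.c_tail_len, d.idol_lens) == (0, 0, ())
        assert tail_length(d) == 0.0 and idol_length(d) is None

    def test_two_domain_hand_computed_segments(self):
        rec = make_record("P1", length=100)
        d = decompose(rec, [hit(21, 40, domain="A"), hit(61, 90, domain="B")])
        assert d.n_tail_len == 20 and d.c_tail_len == 10
        assert d.idol_lens == (20,)
        assert 20 + 20 + 30 + 20 + 10 == 100  # conservation, by hand

    def test_mimivirus_kinase_layout_has_one_idol(self):
        # A 701-aa viral kinase with FYVE followed by PI3_PI4_kinase.
        rec = make_record("Q5UR69", TaxonClass.VIRUS, length=701)
        hits = [DomainHit("Q5UR69", "FYVE", 30, 95),
                DomainHit("Q5UR69", "PI3_PI4_kinase", 420, 690)]
        d = decompose(rec, hits)
        assert len(d.idol_lens) == 1
        assert architecture_string(d) == ["FYVE", "PI3_PI4_kinase"]

    def test_zero_hits_is_an_error(self):
        with pytest.raises(ValueError, match="no domain hits"):
            decompose(make_record("P1"), [])

    def test_conservation_on_random_layouts(self, rng):
        for _ in range(300):
            n_dom = int(rng.integers(1, 6))
            segments = [int(rng.integers(0, 40))]  # n-tail
            hits = []
            pos = segments[0] + 1
            for j in range(n_dom):
                dlen = int(rng.integers(10, 200))
                hits.append(hit(pos, pos + dlen - 1, domain=f"D{j}"))
                pos += dlen
                if j < n_dom - 1:
                    pos += int(rng.integers(0, 60))
            length = hits[-1].end + int(rng.integers(0, 40))
            d = decompose(make_record("P1", length=length), hits)
            total = (d.n_tail_len + d.c_tail_len + sum(d.idol_lens)
                     + sum(e - s + 1 for _, s, e in d.domain_segments))
            assert total == length


class TestLinkerLengths:
    @pytest.mark.parametrize("tails,expected", [((0, 0), 0.0), ((20, 10), 15.0), ((0, 40), 20.0)])
    def test_tail_is_mean_of_two_segments(self, tails, expected):
        rec = make_record("P1", length=tails[0] + tails[1] + 10)
        d = decompose(rec, [hit(tails[0] + 1, tails[0] + 10)])
        assert tail_length(d) == expected

    def test_idol_is_mean_of_internal_linkers(self):
        # linkers 10, 30, 20 between four 10-aa domains
        starts = [1, 21, 61, 91]
        hits = [hit(s, s + 9, domain=f"D{i}") for i, s in enumerate(starts)]
        d = decompose(make_record("P1", length=100), hits)
        assert d.idol_lens == (10, 30, 20)
        assert idol_length(d) == 20.0


class TestInternalLoss:
    def test_mimivirus_vs_slime_mold_architecture(self):
        viral = ["FYVE", "PI3_PI4_kinase"]
        host = ["FYVE", "PI3Ka", "PI3_PI4_kinase"]
        assert detect_internal_loss(viral, host) == [("PI3Ka", 2)]

    def test_swapped_arguments_detect_nothing(self):
        viral = ["FYVE", "PI3_PI4_kinase"]
        host = ["FYVE", "PI3Ka", "PI3_PI4_kinase"]
        assert detect_internal_loss(host, viral) == []

    def test_identical_architectures(self):
        assert detect_internal_loss(["A", "B"], ["A", "B"]) == []

    def test_order_violation_detects_nothing(self):
        assert detect_internal_loss(["A", "C"], ["C", "A", "B"]) == []

    def test_changed_flank_detects_nothing(self):
        assert detect_internal_loss(["A", "B"], ["A", "B", "C"]) == []

    def test_multiple_internal_losses_reported_in_host_order(self):
        assert detect_internal_loss(["A", "D"], ["A", "B", "C", "D"]) == [("B", 2), ("C", 3)]

    def test_repeats_are_positional(self):
        assert detect_internal_loss(["A", "B", "A"], ["A", "B", "C", "A"]) == [("C", 3)]

    def test_agrees_with_exhaustive_subsequence_check_on_random_pairs(self, rng):
        alphabet = ["A", "B", "C", "D"]

        def embeddings(viral, host):
            for combo in itertools.combinations(range(len(host)), len(viral)):
                if [host[i] for i in combo] == list(viral):
                    yield combo

        for _ in range(300):
            viral = [alphabet[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 5)))]
            host = [alphabet[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 7)))]
            result = detect_internal_loss(viral, host)
            pinned = [e for e in embeddings(viral, host)
                      if e and e[0] == 0 and e[-1] == len(host) - 1]
            if result:
                missing_positions = {p - 1 for _, p in result}
                assert len(viral) >= 2 and viral != host
                assert any(set(range(len(host))) - set(e) == missing_positions
                           for e in pinned)
            elif viral != host and len(viral) >= 2:
                # no report => no pinned embedding exists
                assert not pinned or len(viral) == len(host)


class TestFamilySummary:
    def _family(self, viral_specs, meta_specs):
        """specs: list of (length, [domain ids]) with 10-aa domains, 5-aa gaps."""
        records, decs = {}, {}
        fam = Family("F", FamilyType.DOMAIN_FAMILY, set())
        for prefix, specs, taxon in (("v", viral_specs, TaxonClass.VIRUS),
                                     ("m", meta_specs, TaxonClass.METAZOA)):
            for i, (length, domains) in enumerate(specs):
                pid = f"{prefix}{i}"
                fam.member_ids.add(pid)
                records[pid] = make_record(pid, taxon, length)
                hits = []
                pos = 1
                for dom in domains:
                    hits.append(DomainHit(pid, dom, pos, pos + 9))
                    pos += 15
                decs[pid] = decompose(records[pid], hits)
        return fam, records, decs

    def test_identical_proteins_give_unit_ratios(self):
        fam, records, decs = self._family(
            [(50, ["A", "B"])] * 3, [(50, ["A", "B"])] * 3
        )
        summary = summarize_family(fam, records, decs)
        assert summary.ratio_length_m_over_v == pytest.approx(1.0)
        assert summary.ratio_distinct_domains_m_over_v == pytest.approx(1.0)
        assert summary.viral_shorter is False

    def test_distinct_domain_ratio_of_three(self):
        fam, records, decs = self._family(
            [(40, ["A"])] * 4, [(80, ["A", "B", "C"])] * 4
        )
        summary = summarize_family(fam, records, decs)
        assert summary.ratio_distinct_domains_m_over_v == pytest.approx(3.0)
        assert summary.viral_shorter is True
        # single-domain viral proteins have no IDOL
        assert summary.per_class[TaxonClass.VIRUS].mean_idol is None
        assert summary.per_class[TaxonClass.METAZOA].mean_idol is not None

    def test_planted_length_means_recovered(self):
        from hijackscan.synthetic_data import CohortParams, HostArchitectureModel, LinkerModel, generate_family

        # Plant metazoan mean length ~912 aa and viral ~503 aa: three 250-aa
        # domains, metazoan linkers of mean 81, viral copy trimmed by its
        # much shorter linkers plus internal-domain loss.
        params = CohortParams(
            n_families=1,
            members_per_family=(200.0, 200.0),
            host_architecture=HostArchitectureModel(3.0, 250.0, 0.001, n_domains_fixed=3),
            linker_model=LinkerModel(81.0, 5.0, 81.0, 5.0),
            domain_loss_prob=0.9,
            seed=5,
        )
        fd = generate_family(params, 0)
        by_protein = {}
        for h in fd.hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        decs = {pid: decompose(fd.records[pid], hits) for pid, hits in by_protein.items()}
        summary = summarize_family(fd.family, fd.records, decs)
        meta = summary.per_class[TaxonClass.METAZOA]
        viral = summary.per_class[TaxonClass.VIRUS]
        # expected: metazoan 3*250 + 4*81 = 1074? no — two tails + two idols
        # = 250*3 + 81*4 = 1074; viral mostly lost one internal domain:
        # ~0.9*(500 + 4*5... ) — just check the planted ordering and scale.
        assert meta.mean_length > 900
        assert viral.mean_length < 600
        assert summary.viral_shorter is True
        assert summary.ratio_length_m_over_v == pytest.approx(
            meta.mean_length / viral.mean_length
        )

    def test_members_without_hits_are_excluded_and_counted(self):
        fam, records, decs = self._family([(50, ["A"])], [(50, ["A"])])
        records["m_nohit"] = make_record("m_nohit", TaxonClass.METAZOA, 70)
        fam.member_ids.add("m_nohit")
        summary = summarize_family(fam, records, decs)
        assert summary.n_excluded_no_domains == 1
        assert summary.per_class[TaxonClass.METAZOA].n_proteins == 1

    def test_removing_internal_domain_shrinks_length_not_tails(self):
        # Monotonicity: deleting an internal domain (with its linker)
        # strictly decreases length and occurrences, never the tails.
        full_hits = [hit(11, 40, domain="A"), hit(51, 80, domain="B"), hit(91, 120, domain="C")]
        full = decompose(make_record("P1", length=130), full_hits)
        reduced_hits = [hit(11, 40, domain="A"), hit(51, 80, domain="C", )]
        reduced = decompose(make_record("P1", length=90), reduced_hits)
        assert reduced.length < full.length
        assert reduced.n_domains < full.n_domains
        assert (reduced.n_tail_len, reduced.c_tail_len) == (full.n_tail_len, full.c_tail_len)
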