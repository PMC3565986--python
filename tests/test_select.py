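"""Coverage-tier selection, candidate extraction, Boulder-IO export, Tm rules."""

import numpy as np
import pytest

from ssrkit.detect import SSRLocus, find_perfect_ssrs
from ssrkit.io import Contig
from ssrkit.select import (
    CandidateRejected,
    SelectionConfig,
    estimate_tm,
    export_primer3_records,
    extract_candidate,
    extract_candidates,
    filter_contigs,
    select_loci,
)

from _oracles import parse_boulder

CFG = SelectionConfig()


def _contig(cid, length, coverage):
    return Contig(cid, "ACGTG" * (length // 5) + "A" * (length % 5), coverage)


class TestFilterContigs:
    @pytest.mark.parametrize(
        "length,coverage,tier,kept",
        [
            (150, 200.0, 1, False),   # fails strict length > 200 despite depth
            (201, 10.0, 1, True),     # boundary: >200 strict, >=10 inclusive
            (200, 10.0, 1, False),
            (201, 9.99, 1, False),
            (500, 99.9, 2, False),    # tier 2 boundary
            (500, 100.0, 2, True),
        ],
    )
    def test_boundary_semantics(self, length, coverage, tier, kept):
        contig = _contig("c", length, coverage)
        assert (filter_contigs([contig], CFG, tier) == [contig]) is kept

    def test_unknown_coverage_excluded_with_warning(self, caplog):
        contig = _contig("c", 500, None)
        with caplog.at_level("WARNING", logger="ssrkit.select"):
            assert filter_contigs([contig], CFG, 1) == []
        assert any("coverage unknown" in r.message for r in caplog.records)

    def test_tier2_subset_of_tier1(self, rng):
        contigs = [
            _contig(f"c{i}", int(rng.integers(50, 1000)), float(rng.uniform(0, 300)))
            for i in range(200)
        ]
        tier1 = {c.id for c in filter_contigs(contigs, CFG, 1)}
        tier2 = {c.id for c in filter_contigs(contigs, CFG, 2)}
        assert tier2 <= tier1


class TestSelectLoci:
    def _loci(self, spec):
        return [SSRLocus(cid, i * 30, i * 30 + 12, 2, "AG", "AG", 6)
                for i, cid in enumerate(spec)]

    def test_set_arithmetic(self):
        loci = self._loci(["c1"] * 4 + ["c2"] * 3 + ["c3"] * 3)
        kept = select_loci(loci, [_contig("c2", 300, 50), _contig("c3", 300, 50)])
        assert len(kept) == 6
        assert all(l.contig_id in {"c2", "c3"} for l in kept)

    def test_empty_and_identity(self):
        loci = self._loci(["c1", "c2"])
        assert select_loci(loci, []) == []
        assert select_loci(loci, [_contig("c1", 1, 1), _contig("c2", 1, 1)]) == loci


class TestExtractCandidate:
    def _planted(self, left, right, motif="AG", count=7):
        rng = np.random.default_rng(7)
        def bg(n):
            return "".join(rng.choice(["A", "C", "G", "T"], size=n))
        # breaking base on each side keeps the planted run maximal at `left`
        brk = next(b for b in "ACGT" if b not in (motif[0], motif[-1]))
        seq = bg(left - 1) + brk + motif * count + brk + bg(right - 1)
        contig = Contig("c1", seq)
        loci = find_perfect_ssrs(contig)
        (locus,) = [l for l in loci if l.start == left]
        return contig, locus

    def test_template_and_target_arithmetic(self):
        contig, locus = self._planted(400, 400)
        cand = extract_candidate(locus, contig, flank_length=150)
        assert len(cand.template) == 300 + locus.length
        assert cand.flank_lengths == (150, 150)
        a, b = cand.target_span
        assert cand.template[a:b] == contig.sequence[locus.start : locus.end]

    def test_short_flank_rejected(self):
        contig, locus = self._planted(10, 400)
        with pytest.raises(CandidateRejected) as err:
            extract_candidate(locus, contig, flank_length=150, min_flank_length=50)
        assert err.value.reason == "flank_too_short"

    def test_n_in_flank_rejected(self):
        contig, locus = self._planted(100, 100)
        seq = contig.sequence[: locus.start - 5] + "N" + contig.sequence[locus.start - 4 :]
        contig2 = Contig("c1", seq)
        with pytest.raises(CandidateRejected) as err:
            extract_candidate(locus, contig2, flank_length=80)
        assert err.value.reason == "ambiguous_flank"

    def test_neighboring_ssr_in_flank_rejected(self):
        rng = np.random.default_rng(3)
        bg = lambda n: "".join(rng.choice(["A", "C", "G", "T"], size=n))
        seq = bg(99) + "C" + "AG" * 7 + "CC" + "CT" * 7 + "A" + bg(99)
        contig = Contig("c1", seq)
        loci = [l for l in find_perfect_ssrs(contig) if l.start in (100, 116)]
        assert len(loci) == 2
        with pytest.raises(CandidateRejected) as err:
            extract_candidate(loci[0], contig, flank_length=100, other_loci=loci)
        assert err.value.reason == "ssr_in_flank"

    def test_repeat_recovered_from_template(self):
        contig, locus = self._planted(200, 200, motif="CCG", count=5)
        cand = extract_candidate(locus, contig)
        a, b = cand.target_span
        assert cand.template[a:b].startswith("CCG" * 5)


class TestBoulderExport:
    def test_empty(self):
        assert export_primer3_records([]) == ""

    def test_round_trip_through_parser(self, rng):
        contigs, all_loci = [], []
        for i in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=150)) + "AG" * 8 + "".join(
                rng.choice(list("ACGT"), size=150)
            )
            contig = Contig(f"c{i}", seq)
            loci = find_perfect_ssrs(contig)
            contigs.append(contig)
            all_loci.extend(l for l in loci if l.repeat_count >= 8)
        candidates, _ = extract_candidates(all_loci, contigs, 120, 50)
        assert len(candidates) >= 3
        records = parse_boulder(export_primer3_records(candidates, (100, 300)))
        assert len(records) == len(candidates)
        ids = [r["SEQUENCE_ID"] for r in records]
        assert len(set(ids)) == len(ids)
        for record, cand in zip(records, candidates):
            assert record["SEQUENCE_TEMPLATE"] == cand.template
            start, length = map(int, record["SEQUENCE_TARGET"].split(","))
            assert (start, start + length) == cand.target_span
            assert record["PRIMER_PRODUCT_SIZE_RANGE"] == "100-300"


class TestEstimateTm:
    def test_wallace_all_at(self):
        assert estimate_tm("AAAAATTTTT", "wallace") == 20.0

    def test_wallace_mixed(self):
        assert estimate_tm("ACGTACGTACGTACGTACGT", "wallace") == 60.0

    def test_gc_content_formula(self):
        assert estimate_tm("ACGTACGTACGTACGTACGT", "gc_content") == pytest.approx(51.78)

    @pytest.mark.parametrize("bad", ["ACGTACGTA", "A" * 41, "ACGTACGTNN"])
    def test_bounds_and_alphabet(self, bad):
        with pytest.raises(ValueError):
            estimate_tm(bad)
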