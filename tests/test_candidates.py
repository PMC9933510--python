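"""Cross-assembly candidate polymorphic SSR calling."""

import numpy as np
import pytest

from ssrcore import (
    AlignmentFilter,
    SimulationConfig,
    call_candidates,
    extract_flanks,
    find_ssrs,
    generate_assemblies,
    match_flanks,
)
from ssrcore.candidates import FlankPair, _sample_sd


def _unigene(motif="AG", reps=8, up=None, down=None, seed=0):
    """A single unigene with one planted SSR and clean random flanks."""
    rng = np.random.default_rng(seed)
    while True:
        u = up or "".join(rng.choice(list("ACGT"), size=150))
        d = down or "".join(rng.choice(list("ACGT"), size=150))
        seq = u + motif * reps + d
        loci = find_ssrs(seq)
        if (
            len(loci) == 1
            and loci[0].n_repeats == reps
            and loci[0].start == len(u) + 1
            and loci[0].end == len(u) + len(motif) * reps
        ):
            return seq, loci[0], u, d


class TestExtractFlanks:
    def test_locus_at_sequence_start_unusable_when_both_short(self):
        seq = "AG" * 6 + "TTTTT"
        locus = find_ssrs(seq, "u")[0]
        assert locus.start == 1
        pair = extract_flanks(locus, seq, flank_length=100)
        assert pair.up == "" and not pair.usable

    def test_flanks_match_slice_oracle(self):
        seq, locus, up, down = _unigene(seed=1)
        pair = extract_flanks(locus, seq, flank_length=100)
        # direct-slice oracle
        assert pair.up == seq[locus.start - 101 : locus.start - 1] == up[-100:]
        assert pair.down == seq[locus.end : locus.end + 100] == down[:100]
        assert pair.usable

    def test_locus_outside_sequence_errors(self):
        seq, locus, _, _ = _unigene(seed=2)
        with pytest.raises(ValueError, match="outside"):
            extract_flanks(locus, seq[: locus.end - 5], flank_length=50)

    def test_usable_count_on_planted_set(self):
        """550 loci of which 90 sit at sequence edges with both flanks
        short: 460 remain usable."""
        rng = np.random.default_rng(3)
        usable = 0
        for k in range(550):
            if k < 90:
                seq = "AG" * 8 + "".join(rng.choice(list("ACGT"), size=5))
            else:
                seq, _, _, _ = _unigene(seed=100 + k)
            locus = find_ssrs(seq, f"u{k}")[0]
            if extract_flanks(locus, seq, 100).usable:
                usable += 1
        assert usable == 460


class TestMatchFlanks:
    def test_identical_query_perfect_hit(self):
        seq, locus, _, _ = _unigene(seed=4)
        pair = extract_flanks(locus, seq, 100)
        hit = match_flanks(pair, {"q1": seq}, AlignmentFilter())
        assert hit is not None
        assert hit.identity_up == hit.identity_down == 100.0
        assert hit.interval == (locus.start, locus.end)

    def test_heavy_noise_rejected(self):
        """20% flank substitutions leave identity far below 95%."""
        seq, locus, up, down = _unigene(seed=5)
        pair = extract_flanks(locus, seq, 100)
        rng = np.random.default_rng(5)

        def noisy(s):
            out = list(s)
            for i in range(len(out)):
                if rng.random() < 0.2:
                    out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
            return "".join(out)

        query = noisy(up) + "AG" * 8 + noisy(down)
        assert match_flanks(pair, {"q1": query}, AlignmentFilter()) is None

    def test_expanded_allele_interval_length(self):
        """A query allele with two extra repeats widens the enclosed
        interval by exactly two motif lengths."""
        seq, locus, up, down = _unigene(motif="AAG", reps=6, seed=6)
        pair = extract_flanks(locus, seq, 100)
        query = up + "AAG" * 8 + down
        hit = match_flanks(pair, {"q1": query}, AlignmentFilter())
        assert hit is not None
        ref_span = locus.end - locus.start + 1
        assert hit.interval[1] - hit.interval[0] + 1 == ref_span + 2 * 3

    def test_tie_break_lowest_sequence_id(self):
        seq, locus, _, _ = _unigene(seed=7)
        pair = extract_flanks(locus, seq, 100)
        hit = match_flanks(pair, {"q2": seq, "q1": seq}, AlignmentFilter())
        assert hit.sequence_id == "q1"

    def test_empty_query_errors(self):
        seq, locus, _, _ = _unigene(seed=8)
        pair = extract_flanks(locus, seq, 100)
        with pytest.raises(ValueError, match="empty"):
            match_flanks(pair, {}, AlignmentFilter())


class TestCallCandidates:
    def test_identical_assemblies_yield_nothing(self):
        seq, _, _, _ = _unigene(seed=9)
        asm = {"unigene_0": seq}
        assert call_candidates(asm, {"q1": asm, "q2": asm}) == []

    def test_hand_computed_sample_sd(self):
        """Repeat counts (8, 10, 8) across three assemblies: sample SD
        (n-1 denominator) is 1.1547 and the candidate is retained."""
        seq, locus, up, down = _unigene(motif="AG", reps=8, seed=10)
        ref = {"unigene_0": seq}
        q_expanded = {"unigene_0": up + "AG" * 10 + down}
        cands = call_candidates(ref, {"asm1": q_expanded, "asm2": ref})
        assert len(cands) == 1
        cand = cands[0]
        assert cand.repeat_counts == {"reference": 8, "asm1": 10, "asm2": 8}
        assert cand.sd == pytest.approx(1.1547, abs=1e-4)
        assert cand.miss_rate == 0.0

    def test_sample_sd_helper(self):
        assert _sample_sd([8, 10, 8]) == pytest.approx(1.154700538)
        assert _sample_sd([7]) == 0.0

    def test_high_miss_rate_discarded(self):
        """Found in only 1 of 3 query assemblies: miss rate 0.667 > 0.5."""
        seq, locus, up, down = _unigene(motif="AG", reps=8, seed=11)
        ref = {"unigene_0": seq}
        junk = {"unigene_0": "".join(np.random.default_rng(1).choice(list("ACGT"), size=400))}
        queries = {"asm1": {"unigene_0": up + "AG" * 10 + down},
                   "asm2": junk, "asm3": junk}
        assert call_candidates(ref, queries) == []

    def test_reference_without_ssrs_empty(self):
        ref = {"unigene_0": "".join(np.random.default_rng(2).choice(list("ACGT"), size=300))}
        assert find_ssrs(ref["unigene_0"]) == []
        assert call_candidates(ref, {"q": ref}) == []

    def test_exclusion_list_respected(self):
        seq, _, up, down = _unigene(motif="AG", reps=8, seed=12)
        ref = {"unigene_0": seq}
        query = {"unigene_0": up + "AG" * 10 + down}
        assert call_candidates(ref, {"q": query}, exclusion_list={"unigene_0"}) == []

    def test_exact_recovery_of_planted_polymorphisms(self):
        """Zero flank noise, zero dropout: candidate calling recovers
        exactly the truth-polymorphic planted loci."""
        aset = generate_assemblies(
            SimulationConfig(
                n_unigenes=40, n_planted_ssrs=20, repeat_shift_prob=0.5,
                flank_substitution_rate=0.0, dropout_prob=0.0, seed=13,
            )
        )
        ref = aset.assemblies[aset.reference_id]
        queries = {
            k: v for k, v in aset.assemblies.items() if k != aset.reference_id
        }
        cands = call_candidates(ref, queries)
        called = {c.reference_locus.sequence_id for c in cands}
        truth_poly = {t.unigene_id for t in aset.truth if t.polymorphic}
        assert called == truth_poly
        # and the per-assembly repeat counts equal the planted truth
        by_unigene = {c.reference_locus.sequence_id: c for c in cands}
        for t in aset.truth:
            if not t.polymorphic:
                continue
            cand = by_unigene[t.unigene_id]
            for asm, count in t.repeat_counts.items():
                key = "reference" if asm == aset.reference_id else asm
                assert cand.repeat_counts[key] == count

    def test_monotone_in_min_identity(self):
        """Raising the identity threshold never adds candidates."""
        aset = generate_assemblies(
            SimulationConfig(
                n_unigenes=30, n_planted_ssrs=15, repeat_shift_prob=0.8,
                flank_substitution_rate=0.04, dropout_prob=0.0, seed=14,
            )
        )
        ref = aset.assemblies[aset.reference_id]
        queries = {
            k: v for k, v in aset.assemblies.items() if k != aset.reference_id
        }
        counts = []
        for ident in (80.0, 90.0, 95.0, 99.0, 100.0):
            filt = AlignmentFilter(min_identity=ident, min_coverage=80.0)
            counts.append(len(call_candidates(ref, queries, filt=filt)))
        assert counts == sorted(counts, reverse=True)

    def test_sd_and_miss_rate_invariant_to_assembly_order(self):
        aset = generate_assemblies(
            SimulationConfig(
                n_unigenes=20, n_planted_ssrs=10, repeat_shift_prob=0.7,
                dropout_prob=0.1, seed=15,
            )
        )
        ref = aset.assemblies[aset.reference_id]
        queries = {
            k: v for k, v in aset.assemblies.items() if k != aset.reference_id
        }
        fwd = call_candidates(ref, queries)
        rev = call_candidates(ref, dict(reversed(list(queries.items()))))
        stats_fwd = {(c.reference_locus.sequence_id, round(c.sd, 9), c.miss_rate) for c in fwd}
        stats_rev = {(c.reference_locus.sequence_id, round(c.sd, 9), c.miss_rate) for c in rev}
        assert stats_fwd == stats_rev
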