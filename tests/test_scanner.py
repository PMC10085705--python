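"""Pattern compilation, exhaustive scanning, strand mapping, cleavage prediction."""

import itertools

import numpy as np
import pytest

from permotif import (
    MutationPolicy,
    ScanConfig,
    compile_pattern,
    enumerate_permutations,
    layout_for,
    matches_to_table,
    plant_in_background,
    predict_cleavage,
    reverse_complement,
    sample_instance,
    scan,
    scan_fasta,
    scan_sequence,
    verify_match,
)
from permotif.descriptor import IUPAC_SETS, WATSON_CRICK, WOBBLE


# ---------------------------------------------------------------------------
# independent oracle: enumerate every span assignment, check constraints whole
# ---------------------------------------------------------------------------

def oracle_scan(seq, pattern):
    """All (start, element spans) satisfying the pattern, by full enumeration."""
    s = seq.upper().replace("T", "U")
    L = len(s)
    units = pattern.units
    # length choices per unit; second stem halves tied to first below
    choices = []
    for u in units:
        if u.kind == "stem_half":
            fi, si = pattern.stem_pairs[u.stem_id]
            if u.index == si:
                choices.append(("tied", u.stem_id))
                continue
        choices.append(("free", list(range(u.min_len, u.max_len + 1))))
    found = set()
    free_idx = [i for i, c in enumerate(choices) if c[0] == "free"]
    for start in range(L + 1):
        for combo in itertools.product(*(choices[i][1] for i in free_idx)):
            lens = {}
            for i, k in zip(free_idx, combo):
                lens[i] = k
            for i, c in enumerate(choices):
                if c[0] == "tied":
                    fi, _si = pattern.stem_pairs[c[1]]
                    lens[i] = lens[fi]
            spans = []
            pos = start
            for u in units:
                spans.append((pos, pos + lens[u.index]))
                pos += lens[u.index]
            if pos > L:
                continue
            if _oracle_check(s, pattern, spans):
                found.add(
                    (start, tuple((u.name, a, b) for u, (a, b) in zip(units, spans)))
                )
    return found


def _oracle_check(s, pattern, spans):
    for u, (a, b) in zip(pattern.units, spans):
        if u.kind == "literal":
            for m, c in enumerate(u.literal):
                ch = s[a + m]
                if ch not in "ACGU" or ch not in IUPAC_SETS[c]:
                    return False
    for sid, (fi, si) in pattern.stem_pairs.items():
        spec = pattern.stem_specs[sid]
        (a0, a1), (b0, b1) = spans[fi], spans[si]
        k = a1 - a0
        bad = 0
        for m in range(k):
            pair = (s[a0 + m], s[b0 + k - 1 - m])
            if pair in WATSON_CRICK or (spec.wobble_allowed and pair in WOBBLE):
                continue
            bad += 1
        if bad > spec.mismatch_budget:
            return False
    return True


class TestCompile:
    def test_min_length_arithmetic(self, hammerhead):
        for lay in enumerate_permutations(hammerhead):
            pat = compile_pattern(hammerhead, lay)
            lit_len = sum(
                len(u.literal) for u in pat.units if u.kind == "literal"
            )
            stem_min = sum(
                spec.min_len for spec in pat.stem_specs.values()
            )
            assert pat.min_total >= lit_len + 2 * stem_min

    def test_sgc_pattern_is_pseudoknotted_csg_counterpart_too(self, hammerhead):
        from permotif import count_pseudoknots

        for order, expected in [("SGC", 3), ("SCG", 0)]:
            lay = layout_for(hammerhead, order)
            pat = compile_pattern(hammerhead, lay)
            assert len(pat.stem_specs) == 3
            assert count_pseudoknots(lay).crossing_pairs == expected

    def test_unbounded_spacer_rejected(self, hammerhead):
        # the grammar cannot express an unbounded spacer, so exercise the
        # compile-level guard directly
        from permotif.descriptor import MotifElement

        with pytest.raises(ValueError):
            MotifElement(kind="spacer", length_range=(3, None))


class TestScan:
    def test_empty_sequence_yields_no_matches(self, hammerhead, sgc_layout):
        pat = compile_pattern(hammerhead, sgc_layout)
        assert scan("", pat) == []

    def test_planted_instance_recovered_exactly(self, hammerhead, sgc_layout):
        pat = compile_pattern(hammerhead, sgc_layout)
        seq, truth = sample_instance(hammerhead, sgc_layout, seed=42)
        ms = scan(seq, pat)
        assert any(m.element_spans == truth.element_spans for m in ms)
        assert all(verify_match(seq, pat, m) for m in ms)

    def test_m1_mutation_abolishes_matching(self, hammerhead, sgc_layout):
        # changing the highly conserved G within the first part of CUGAnGA
        pat = compile_pattern(hammerhead, sgc_layout)
        for seed in range(10):
            seq, truth = sample_instance(hammerhead, sgc_layout, seed=seed)
            a, _b = next(
                (s, e) for n, s, e in truth.element_spans if n == "C.seq:CUGANGA"
            )
            assert seq[a + 2] == "G"
            mutated = seq[: a + 2] + "A" + seq[a + 3 :]
            assert scan(mutated, pat) == []

    def test_compensatory_mutations_preserve_matching(self, hammerhead, sgc_layout):
        pat = compile_pattern(hammerhead, sgc_layout)
        policy = MutationPolicy(kind="compensatory", rate=0.5)
        for seed in range(25):
            seq, truth = sample_instance(
                hammerhead, sgc_layout, seed=seed, policy=policy
            )
            ms = scan(seq, pat)
            assert any(m.element_spans == truth.element_spans for m in ms)

    def test_pair_breaking_mutations_beyond_budget_kill_matching(
        self, hammerhead, sgc_layout
    ):
        pat = compile_pattern(hammerhead, sgc_layout)
        policy = MutationPolicy(kind="breaking", count=1)
        for seed in range(25):
            seq, truth = sample_instance(
                hammerhead, sgc_layout, seed=seed, policy=policy
            )
            # the planted placement itself must be gone (budget is 0);
            # other placements may still exist by chance
            assert not any(
                m.element_spans == truth.element_spans for m in scan(seq, pat)
            )

    def test_matches_sorted_and_deduplicated(self, mini):
        lay = layout_for(mini, "AB")
        pat = compile_pattern(mini, lay)
        rng = np.random.default_rng(5)
        seq, _ = sample_instance(mini, lay, seed=rng)
        seq = seq + seq  # two copies -> multiple matches
        ms = scan(seq, pat)
        keys = [(m.start, m.type_name, m.end, m.element_spans) for m in ms]
        assert keys == sorted(keys)
        assert len(set(keys)) == len(keys)

    def test_scan_agrees_with_enumeration_oracle(self, mini):
        lay = layout_for(mini, "AB")
        pat = compile_pattern(mini, lay)
        rng = np.random.default_rng(11)
        hits = 0
        for trial in range(60):
            if trial % 3 == 0:
                inst, _ = sample_instance(mini, lay, seed=rng)
                pad = "".join(rng.choice(list("ACGU"), size=30))
                seq = pad[:15] + inst + pad[15:]
            else:
                seq = "".join(rng.choice(list("ACGU"), size=60))
            got = {
                (m.start, m.element_spans) for m in scan(seq, pat)
            }
            expected = oracle_scan(seq, pat)
            assert got == expected
            hits += len(got)
        assert hits > 0  # the comparison exercised real matches

    def test_strand_symmetry(self, hammerhead, sgc_layout):
        pat = compile_pattern(hammerhead, sgc_layout)
        seq, _ = sample_instance(hammerhead, sgc_layout, seed=3)
        fwd = scan(seq, pat)
        # scanning the reverse complement and mapping back must reproduce
        # the forward matches' spans
        rc = reverse_complement(seq)
        L = len(seq)
        back = {(L - m.end, L - m.start) for m in scan(rc, pat)}
        both = scan_sequence(seq, [pat], ScanConfig(both_strands=True))
        minus = {(m.start, m.end) for m in both if m.strand == "-"}
        assert back == minus
        plus = {(m.start, m.end) for m in both if m.strand == "+"}
        assert plus == {(m.start, m.end) for m in fwd}


class TestScanFasta:
    def test_minus_strand_plant_mapped_to_forward(
        self, tmp_path, hammerhead, csg_layout
    ):
        from permotif.io import write_fasta

        rng = np.random.default_rng(9)
        inst, truth = sample_instance(hammerhead, csg_layout, seed=rng)
        records, truths = plant_in_background(
            [(inst, truth)], n_decoys=0, seed=21, host_length=160,
            random_strand=False,
        )
        # force a minus-strand plant by reverse-complementing the host
        sid, seq = records[0]
        tr = truths[0]
        L = len(seq)
        path = tmp_path / "minus.fa"
        write_fasta([(sid, reverse_complement(seq))], path)
        ms = scan_fasta(path, hammerhead, type_names=["CSG"])
        minus = [m for m in ms if m.strand == "-"]
        assert any(
            (m.start, m.end) == (L - tr.span[1], L - tr.span[0]) for m in minus
        )

    def test_duplicate_record_ids_rejected(self, tmp_path, hammerhead):
        path = tmp_path / "dup.fa"
        path.write_text(">a\nACGU\n>a\nACGU\n")
        with pytest.raises(ValueError, match="duplicate record ID"):
            scan_fasta(path, hammerhead, type_names=["SGC"])

    def test_background_matches_all_reverify(self, tmp_path, mini):
        from permotif.io import write_fasta

        lay = layout_for(mini, "AB")
        pat = compile_pattern(mini, lay)
        rng = np.random.default_rng(33)
        records = [
            (f"bg_{i:03d}", "".join(rng.choice(list("ACGU"), size=120)))
            for i in range(100)
        ]
        path = tmp_path / "bg.fa"
        write_fasta(records, path)
        ms = scan_fasta(path, mini, type_names=["AB"])
        seqs = dict(records)
        for m in ms:
            assert verify_match(seqs[m.sequence_id], pat, m)

    def test_match_table_is_bed_like(self, mini, tmp_path):
        from permotif.io import write_fasta

        lay = layout_for(mini, "AB")
        inst, _ = sample_instance(mini, lay, seed=2)
        path = tmp_path / "one.fa"
        write_fasta([("rec", inst)], path)
        table = matches_to_table(scan_fasta(path, mini, type_names=["AB"]))
        assert list(table.columns) == [
            "seq_id", "start", "end", "name", "score", "strand", "elements",
        ]
        assert (table["name"] == "AB").all()


class TestCleavagePrediction:
    def _construct_with_site(self, descriptor, order, target_site, total_len, seed):
        """Embed an instance so its predicted cleavage falls at target_site."""
        lay = layout_for(descriptor, order)
        rng = np.random.default_rng(seed)
        inst, truth = sample_instance(descriptor, lay, seed=rng)
        offset = target_site - truth.cleavage
        assert offset >= 0 and offset + len(inst) <= total_len
        bg = "".join(rng.choice(list("ACGU"), size=total_len))
        construct = bg[:offset] + inst + bg[offset + len(inst):]
        pat = compile_pattern(descriptor, lay)
        ms = [m for m in scan(construct, pat) if m.predicted_cleavage == target_site]
        assert ms, "planted cleavage site not recovered"
        return construct, ms[0]

    def test_sgc_analog_fragments_15_and_64(self, hammerhead):
        # synthetic analog of a 79-nt SGC construct cleaving after position 15
        construct, m = self._construct_with_site(hammerhead, "SGC", 15, 79, seed=4)
        prod = predict_cleavage(m, construct)
        assert (prod.five_prime_len, prod.three_prime_len) == (15, 64)
        assert not prod.degenerate

    def test_csg_analog_fragments_48_and_29(self, hammerhead):
        # synthetic analog of a 77-nt CSG construct cleaving after position 48
        construct, m = self._construct_with_site(hammerhead, "CSG", 48, 77, seed=8)
        prod = predict_cleavage(m, construct)
        assert (prod.five_prime_len, prod.three_prime_len) == (48, 29)

    def test_fragments_sum_to_construct_length(self, hammerhead, sgc_layout):
        pat = compile_pattern(hammerhead, sgc_layout)
        rng = np.random.default_rng(17)
        for _ in range(10):
            inst, truth = sample_instance(hammerhead, sgc_layout, seed=rng)
            pad = "".join(rng.choice(list("ACGU"), size=40))
            construct = pad[:20] + inst + pad[20:]
            for m in scan(construct, pat):
                prod = predict_cleavage(m, construct)
                assert prod.five_prime_len + prod.three_prime_len == len(construct)

    def test_site_zero_flagged_degenerate(self, mini):
        # a match whose cleavage marker sits at the very start of the construct
        from permotif.scanner import Match

        m = Match(
            sequence_id="x", strand="+", start=0, end=10, type_name="AB",
            element_spans=(), predicted_cleavage=0,
        )
        prod = predict_cleavage(m, "ACGUACGUAC")
        assert prod.degenerate and prod.five_prime_len == 0

    def test_missing_cleavage_site_is_an_error(self, mini):
        lay = layout_for(mini, "AB")
        pat = compile_pattern(mini, lay)
        seq, _ = sample_instance(mini, lay, seed=1)
        m = scan(seq, pat)[0]
        with pytest.raises(ValueError, match="no cleavage site"):
            predict_cleavage(m, seq)
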