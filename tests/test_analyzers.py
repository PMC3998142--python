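"""Pattern/profile scanners against brute-force oracles, and the
clan-overlap post-processing rule."""

import itertools
import random

import numpy as np
import pytest

from sigscan.analyzers import (AA20, PatternSyntaxError, ProfileModel,
                               parse_pattern, resolve_overlaps,
                               run_analysis, scan_filter_analyzer,
                               scan_pattern, scan_profile,
                               single_pass_analyzer)
from sigscan.model import (FILTERED_IN, FILTERED_OUT, Location, Match,
                           Signature, canonicalize_and_checksum)


def prot(residues, pid="p"):
    return canonicalize_and_checksum(pid, residues)


# ---------------------------------------------------------------------------
# independent oracles

def oracle_scan_pattern(seq: str, model):
    """Brute force: expand every repeat-count combination into a
    fixed-length element list and test every window directly, keeping
    the shortest accepting window per start."""
    expansions = []
    for combo in itertools.product(
            *[range(e.min_count, e.max_count + 1) for e in model.elements]):
        elems = []
        for e, c in zip(model.elements, combo):
            elems.extend([e] * c)
        expansions.append(elems)
    out = []
    starts = [0] if model.anchored_start else range(len(seq))
    for s in starts:
        best = None
        for elems in expansions:
            L = len(elems)
            if L == 0 or s + L > len(seq):
                continue
            if model.anchored_end and s + L != len(seq):
                continue
            if all(e.accepts(seq[s + i]) for i, e in enumerate(elems)):
                if best is None or L < best:
                    best = L
        if best is not None:
            out.append((s + 1, s + best))
    return out


def oracle_scan_profile(seq: str, matrix, threshold):
    L = matrix.shape[0]
    out = []
    for j in range(len(seq) - L + 1):
        score = 0.0
        for i in range(L):
            ch = seq[j + i]
            if ch in AA20:
                score += matrix[i, AA20.index(ch)]
        if score >= threshold:
            out.append((j + 1, j + L, score))
    return out


def random_pattern(rng):
    parts = []
    for _ in range(rng.randint(2, 4)):
        kind = rng.random()
        if kind < 0.35:
            elem = rng.choice(AA20)
        elif kind < 0.6:
            elem = "x"
        elif kind < 0.8:
            elem = "[" + "".join(rng.sample(AA20, rng.randint(1, 3))) + "]"
        else:
            elem = "{" + "".join(rng.sample(AA20, rng.randint(1, 3))) + "}"
        r = rng.random()
        if r < 0.25:
            m = rng.randint(0, 2)
            elem += f"({m},{m + rng.randint(0, 2)})"
        elif r < 0.4:
            elem += f"({rng.randint(1, 3)})"
        parts.append(elem)
    pat = "-".join(parts)
    if rng.random() < 0.1:
        pat = "<" + pat
    if rng.random() < 0.1:
        pat = pat + ">"
    return pat


# ---------------------------------------------------------------------------
# pattern scanner

class TestPatternScanner:
    def test_fixed_gap_pattern(self):
        model = parse_pattern("C-x(2)-C")
        locs = scan_pattern(prot("ACKLCA"), model)
        assert [(l.start, l.stop) for l in locs] == [(2, 5)]

    def test_n_terminal_anchor(self):
        model = parse_pattern("<M")
        assert [(l.start, l.stop)
                for l in scan_pattern(prot("MKV"), model)] == [(1, 1)]
        assert scan_pattern(prot("KMV"), model) == []

    def test_c_terminal_anchor(self):
        model = parse_pattern("K-V>")
        assert [(l.start, l.stop)
                for l in scan_pattern(prot("MKV"), model)] == [(2, 3)]
        assert scan_pattern(prot("MKVA"), model) == []

    def test_multiple_occurrences_reported_leftmost_first(self):
        model = parse_pattern("[DE]-x-K")
        locs = scan_pattern(prot("DAKEAK"), model)
        assert [(l.start, l.stop) for l in locs] == [(1, 3), (4, 6)]

    def test_scores_absent(self):
        locs = scan_pattern(prot("ACKLCA"), parse_pattern("C-x(2)-C"))
        assert all(l.score is None for l in locs)

    @pytest.mark.parametrize("bad, pos", [
        ("C-[DE", 2), ("C-(2)", 2), ("", 0), ("C-{D", 2),
    ])
    def test_malformed_pattern_reports_position(self, bad, pos):
        with pytest.raises(PatternSyntaxError) as exc:
            parse_pattern(bad)
        assert exc.value.position == pos

    def test_ranged_repeat_reports_shortest_window(self):
        model = parse_pattern("G-x(1,3)-G")
        locs = scan_pattern(prot("GAGAAG"), model)
        assert (1, 3) in [(l.start, l.stop) for l in locs]

    def test_agrees_with_brute_force_on_random_cases(self):
        rng = random.Random(2024)
        for _ in range(400):
            pat = random_pattern(rng)
            model = parse_pattern(pat)
            seq = "".join(rng.choice(AA20) for _ in range(rng.randint(5, 40)))
            got = [(l.start, l.stop) for l in scan_pattern(prot(seq), model)]
            assert got == oracle_scan_pattern(seq, model), \
                f"pattern {pat} on {seq}"


# ---------------------------------------------------------------------------
# profile scanner

class TestProfileScanner:
    def _model(self, rows, threshold):
        m = np.zeros((len(rows), 20))
        for i, (aa, score) in enumerate(rows):
            m[i, AA20.index(aa)] = score
        return ProfileModel(matrix=m, threshold=threshold)

    def test_threshold_hit_windows(self):
        model = self._model([("M", 5.0), ("A", 5.0)], 10.0)
        locs = scan_profile(prot("MAMA"), model)
        assert [(l.start, l.stop, l.score) for l in locs] == \
            [(1, 2, 10.0), (3, 4, 10.0)]

    def test_threshold_monotonicity(self):
        lo = self._model([("M", 5.0), ("A", 5.0)], 10.0)
        hi = self._model([("M", 5.0), ("A", 5.0)], 11.0)
        assert scan_profile(prot("MAMA"), hi) == []
        for seq in ("MAMAMA", "AAMMAA", "MMMMAA"):
            lo_locs = {(l.start, l.stop)
                       for l in scan_profile(prot(seq), lo)}
            hi_locs = {(l.start, l.stop)
                       for l in scan_profile(prot(seq), hi)}
            assert hi_locs <= lo_locs

    def test_zero_matrix_zero_threshold_reports_every_window(self):
        model = ProfileModel(matrix=np.zeros((2, 20)), threshold=0.0)
        locs = scan_profile(prot("MAW"), model)
        assert [(l.start, l.stop, l.score) for l in locs] == \
            [(1, 2, 0.0), (2, 3, 0.0)]

    def test_short_protein_yields_empty(self):
        model = ProfileModel(matrix=np.zeros((5, 20)), threshold=0.0)
        assert scan_profile(prot("MA"), model) == []

    def test_agrees_with_window_sum_oracle_on_random_cases(self):
        rng = random.Random(99)
        for _ in range(300):
            L = rng.randint(1, 6)
            matrix = np.round(
                np.array([[rng.uniform(-3, 5) for _ in range(20)]
                          for _ in range(L)]), 2)
            threshold = rng.uniform(-2, 8)
            model = ProfileModel(matrix=matrix, threshold=threshold)
            seq = "".join(rng.choice(AA20 + "X")
                          for _ in range(rng.randint(1, 30)))
            got = [(l.start, l.stop, round(l.score, 6))
                   for l in scan_profile(prot(seq), model)]
            want = [(s, e, round(sc, 6))
                    for s, e, sc in oracle_scan_profile(seq, matrix,
                                                        threshold)]
            assert got == want


# ---------------------------------------------------------------------------
# overlap resolution

def sig(acc, clan=None):
    return Signature(accession=acc, name=acc, library="L",
                     library_version="1", model_kind="pattern",
                     model_payload=parse_pattern("A"), clan=clan)


def match(acc, *locs, md5="m" * 32):
    return Match(protein_md5=md5, signature_accession=acc,
                 locations=tuple(Location(*l) for l in locs))


class TestResolveOverlaps:
    def test_best_scoring_overlapping_match_wins(self):
        sigs = {"A": sig("A", "CL"), "B": sig("B", "CL")}
        out = resolve_overlaps(
            [match("A", (1, 10, 8.0)), match("B", (5, 15, 3.0))], sigs)
        assert [m.status for m in out] == [FILTERED_IN, FILTERED_OUT]

    def test_non_overlapping_clan_members_both_survive(self):
        sigs = {"A": sig("A", "CL"), "B": sig("B", "CL")}
        out = resolve_overlaps(
            [match("A", (1, 10, 1.0)), match("B", (20, 30, 1.0))], sigs)
        assert all(m.status == FILTERED_IN for m in out)

    def test_tie_break_chain_ends_at_accession(self):
        sigs = {"PF001": sig("PF001", "CL"), "PF002": sig("PF002", "CL")}
        out = resolve_overlaps(
            [match("PF002", (1, 10, 5.0)), match("PF001", (1, 10, 5.0))],
            sigs)
        by_acc = {m.signature_accession: m.status for m in out}
        assert by_acc == {"PF001": FILTERED_IN, "PF002": FILTERED_OUT}

    def test_clanless_matches_always_survive(self):
        sigs = {"A": sig("A"), "B": sig("B")}
        out = resolve_overlaps(
            [match("A", (1, 10, 1.0)), match("B", (1, 10, 9.0))], sigs)
        assert all(m.status == FILTERED_IN for m in out)

    def test_conserves_match_count_and_is_idempotent(self):
        sigs = {"A": sig("A", "CL"), "B": sig("B", "CL"), "C": sig("C")}
        matches = [match("A", (1, 10, 8.0)), match("B", (5, 15, 3.0)),
                   match("C", (2, 4))]
        out = resolve_overlaps(matches, sigs)
        assert len(out) == len(matches)
        again = resolve_overlaps(out, sigs)
        assert [(m.signature_accession, m.status) for m in again] == \
            [(m.signature_accession, m.status) for m in out]

    def test_multi_location_match_survives_if_any_location_survives(self):
        sigs = {"A": sig("A", "CL"), "B": sig("B", "CL")}
        out = resolve_overlaps(
            [match("A", (1, 10, 9.0)),
             match("B", (5, 8, 1.0), (50, 60, 1.0))], sigs)
        by_acc = {m.signature_accession: m.status for m in out}
        assert by_acc["A"] == FILTERED_IN
        assert by_acc["B"] == FILTERED_IN  # second location is clear

    def test_mixed_proteins_rejected(self):
        with pytest.raises(ValueError):
            resolve_overlaps([match("A", (1, 2), md5="a" * 32),
                              match("B", (1, 2), md5="b" * 32)], {})


# ---------------------------------------------------------------------------
# analyzer contract

class TestRunAnalysis:
    def _sigs(self):
        return [Signature("S1", "s1", "L", "1", "pattern",
                          parse_pattern("C-x(2)-C-H"), clan=None)]

    def test_empty_protein_set(self):
        assert run_analysis([], self._sigs(),
                            scan_filter_analyzer("L")) == []

    def test_single_pass_modality_passes_raw_through(self):
        p = prot("ACAACHCAACH")
        out = run_analysis([p], self._sigs(), single_pass_analyzer("L"))
        assert out and all(m.status == FILTERED_IN for m in out)

    def test_mixed_library_rejected(self):
        sigs = self._sigs() + [Signature("S2", "s2", "OTHER", "1",
                                         "pattern", parse_pattern("A"),
                                         clan=None)]
        with pytest.raises(ValueError):
            run_analysis([], sigs, scan_filter_analyzer("L"))
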