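"""Target-prediction tests: seed rules, alignment scoring vs a brute-force
dynamic-programming oracle, duplex energies, and transcriptome scanning."""

import numpy as np
import pytest

from cernaforge import synthetic as syn
from cernaforge import targets as tp

# ---------------------------------------------------------------------------
# independent oracle: Waterman-Smith-Beyer local alignment with explicit
# gap-length maximization (no affine state machine)
# ---------------------------------------------------------------------------


def oracle_align_score(mirna: str, site: str) -> float:
    x = tp.to_rna(mirna)
    y = tp.to_rna(site)[::-1]  # antiparallel

    def sub(i: int, j: int) -> float:
        a, b = x[i], y[j]
        if (a, b) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
            s = 5.0
        elif (a, b) in {("G", "U"), ("U", "G")}:
            s = 1.0
        else:
            s = -3.0
        return 2.0 * s if 1 <= i <= 7 else s  # miRNA positions 2-8, 0-based 1-7

    nx_, ny_ = len(x), len(y)
    H = [[0.0] * (ny_ + 1) for _ in range(nx_ + 1)]
    best = 0.0
    for i in range(1, nx_ + 1):
        for j in range(1, ny_ + 1):
            cand = max(0.0, H[i - 1][j - 1] + sub(i - 1, j - 1))
            for k in range(1, i + 1):
                cand = max(cand, H[i - k][j] + (-9.0 - 4.0 * (k - 1)))
            for k in range(1, j + 1):
                cand = max(cand, H[i][j - k] + (-9.0 - 4.0 * (k - 1)))
            H[i][j] = cand
            best = max(best, cand)
    return best


def brute_force_scan(mirna_id, mirna, t_id, transcript, cls, s_min, g_max, circular=False):
    """All-offsets scan: test the seed rule at every window via seed_match
    (no 7-mer string search) and keep windows passing both thresholds."""
    m = tp.to_rna(mirna)
    t = tp.to_rna(transcript)
    n = len(t)
    lw = len(m) + tp.SCAN_SLACK
    pad = min(lw - 1, n) if circular else 0
    scan_seq = t[n - pad :] + t + t[:pad] if circular else t
    hits = []
    for q in range(pad, pad + n):  # seed block start, one per original offset
        e = q + 8
        if e > len(scan_seq):
            continue
        s = max(0, e - lw)
        window = scan_seq[s:e]
        if not tp.seed_match(m, window):
            continue
        aln = tp.align_mirna_site(m, window)
        if aln.score < s_min:
            continue
        dg = tp.alignment_energy(m, window, aln)
        if dg > g_max:
            continue
        site_positions = [j for _, j, kind in aln.columns if j is not None]
        start0 = s + min(site_positions) - pad
        end0 = s + max(site_positions) - pad
        hits.append(
            {
                "mirna_id": mirna_id,
                "transcript_id": t_id,
                "transcript_class": cls,
                "site_start": start0 % n + 1,
                "site_end": end0 % n + 1,
                "linear_start": start0,
                "linear_end": end0,
                "score_S": aln.score,
                "delta_G": dg,
                "seed_matched": True,
                "junction_spanning": bool(circular and (start0 < 0 or end0 >= n)),
            }
        )
    return tp._collapse_overlaps(hits)


def _random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))


# ---------------------------------------------------------------------------
# seed matching
# ---------------------------------------------------------------------------


class TestSeedMatch:
    def test_constructed_complement_matches(self):
        # miRNA 5'-A GGAAUGU ...-3'; seed (pos 2-8) GGAAUGU pairs ACAUUCC
        mirna = "AGGAAUGUCCCCCCCCCCCCCCC"
        window = "GGGGGGGGGGGGGGGACAUUCCU"
        assert tp.seed_match(mirna, window)

    def test_single_seed_mismatch_fails(self):
        mirna = "AGGAAUGUCCCCCCCCCCCCCCC"
        window = "GGGGGGGGGGGGGGGACAAUCCU"  # one seed-position mismatch
        assert not tp.seed_match(mirna, window)

    def test_gu_wobble_in_seed_fails_strict_pairing(self):
        # seed G at miRNA position 2 over target U: a wobble, not Watson-Crick
        mirna = "AGGAAUGUCCCCCCCCCCCCCCC"
        window = "GGGGGGGGGGGGGGGACAUUCUU"
        assert not tp.seed_match(mirna, window)

    def test_dna_input_is_mapped_to_rna(self):
        assert tp.seed_match("AGGAATGTCCCCCCCCCCCCCCC", "GGGGGGGGGGGGGGGACATTCCT")

    def test_non_nucleotide_symbols_rejected(self):
        with pytest.raises(ValueError, match="non-AUCG"):
            tp.seed_match("AGGAANGUCCCCCCCCCCCCCCC", "ACAUUCCU")


# ---------------------------------------------------------------------------
# alignment scoring
# ---------------------------------------------------------------------------


class TestAlignScore:
    def test_perfect_complement_score_formula(self, rng):
        # full-length complement: 5 per position plus 5 extra per seed position
        for length in (20, 22, 23, 25):
            m = _random_rna(rng, length)
            site = tp.revcomp_rna(m)
            assert tp.align_score(m, site) == pytest.approx(5.0 * length + 5.0 * 7)

    def test_matches_brute_force_oracle_on_random_pairs(self, rng):
        for _ in range(40):
            m = _random_rna(rng, int(rng.integers(8, 18)))
            site = _random_rna(rng, int(rng.integers(4, 18)))
            assert tp.align_score(m, site) == pytest.approx(oracle_align_score(m, site))

    def test_matches_oracle_on_near_complements(self, rng):
        # mutated complements exercise mismatches and gaps
        for _ in range(25):
            m = _random_rna(rng, int(rng.integers(12, 24)))
            site = list(tp.revcomp_rna(m))
            for _ in range(int(rng.integers(1, 4))):
                pos = int(rng.integers(0, len(site)))
                site[pos] = str(rng.choice(list("ACGU")))
            if rng.random() < 0.5:  # also delete a base -> gap
                del site[int(rng.integers(1, len(site) - 1))]
            site = "".join(site)
            assert tp.align_score(m, site) == pytest.approx(oracle_align_score(m, site))

    def test_score_invariant_to_flanking_sequence(self, rng):
        m = _random_rna(rng, 22)
        site = tp.revcomp_rna(m)
        flanked = "CCCCCCCCCC" + site + "GGGGGGGGGG"
        assert tp.align_score(m, flanked) >= tp.align_score(m, site)
        assert tp.align_score(m, flanked) == pytest.approx(oracle_align_score(m, flanked))

    def test_empty_site_raises(self):
        with pytest.raises(ValueError, match="empty site"):
            tp.align_score("ACGUACGUACGUACGUACGUACG", "")


# ---------------------------------------------------------------------------
# duplex energy
# ---------------------------------------------------------------------------


class TestDuplexEnergy:
    def test_no_pairing_leaves_initiation_penalty_only(self):
        dg = tp.duplex_energy("A" * 23, "A" * 23)
        assert dg == pytest.approx(tp.INITIATION_DG)
        assert dg > -30

    def test_homopolymer_perfect_duplex_hand_sum(self):
        # 23 G:C pairs -> 22 GG/CC stacks of -3.26 plus initiation 4.09
        dg = tp.duplex_energy("G" * 23, "C" * 23)
        assert dg == pytest.approx(4.09 + 22 * -3.26)
        assert dg <= -30

    def test_patterned_perfect_duplex_hand_sum(self):
        # (ACGU)x5 + ACG: stacks 6xAC/UG, 6xCG/GC, 5xGU/CA, 5xUA/AU
        m = "ACGU" * 5 + "ACG"
        dg = tp.duplex_energy(m, tp.revcomp_rna(m))
        expected = 4.09 + 6 * -2.24 + 6 * -2.36 + 5 * -2.24 + 5 * -1.33
        assert dg == pytest.approx(expected)

    def test_breaking_internal_stack_raises_energy(self, rng):
        m = "ACGU" * 5 + "ACG"
        site = tp.revcomp_rna(m)
        perfect = tp.duplex_energy(m, site)
        # break the pair at an internal position
        broken = site[:11] + ("A" if site[11] != "A" else "G") + site[12:]
        assert tp.duplex_energy(m, broken) > perfect

    def test_full_length_perfect_duplexes_pass_threshold(self, rng):
        for _ in range(10):
            m = syn._draw_mirna(rng)
            assert tp.duplex_energy(m, syn._dna_site_for(m)) <= -30.0


# ---------------------------------------------------------------------------
# transcriptome scanning
# ---------------------------------------------------------------------------


class TestScan:
    def test_equivalence_with_all_offsets_brute_force(self, rng):
        mirnas = {f"mir{i}": syn._draw_mirna(rng) for i in range(3)}
        transcripts = {}
        for i in range(4):
            seq = syn._random_dna(rng, 400)
            # plant one site for a random miRNA
            mid = str(rng.choice(list(mirnas)))
            site = syn._dna_site_for(mirnas[mid])
            pos = int(rng.integers(0, len(seq) - len(site)))
            transcripts[f"t{i}"] = seq[:pos] + site + seq[pos + len(site) :]
        got = tp.scan_transcriptome(mirnas, transcripts, "mRNA")
        expected = []
        for t_id, t_seq in transcripts.items():
            for m_id, m_seq in mirnas.items():
                expected.extend(
                    brute_force_scan(m_id, m_seq, t_id, t_seq, "mRNA", 150.0, -30.0)
                )
        got_set = {
            (r.mirna_id, r.transcript_id, r.site_start, r.site_end, r.score_S)
            for r in got.itertuples()
        }
        exp_set = {
            (h["mirna_id"], h["transcript_id"], h["site_start"], h["site_end"], h["score_S"])
            for h in expected
        }
        assert got_set == exp_set
        assert len(got) >= 4  # the planted sites are all found

    def test_score_just_below_threshold_excluded(self, rng):
        # a 23-nt perfect complement scores exactly 150; one non-seed mismatch
        # drops it to 142 and out of the report
        while True:
            m = syn._draw_mirna(rng)
            if len(m) == 23:
                break
        site = syn._dna_site_for(m)
        assert tp.align_score(m, site) == pytest.approx(150.0)
        broken = site[:2] + ("A" if site[2] != "A" else "G") + site[3:]  # miRNA 3' region
        assert tp.align_score(m, broken) < 150.0
        host = syn._random_dna(rng, 150) + broken + syn._random_dna(rng, 150)
        hits = tp.scan_transcriptome({"m": m}, {"t": host}, "mRNA")
        assert len(hits) == 0
        host_ok = syn._random_dna(rng, 150) + site + syn._random_dna(rng, 150)
        hits_ok = tp.scan_transcriptome({"m": m}, {"t": host_ok}, "mRNA")
        assert len(hits_ok) == 1

    def test_empty_mirna_set_gives_empty_hits(self):
        hits = tp.scan_transcriptome({}, {"t": "ACGT" * 50}, "mRNA")
        assert len(hits) == 0
        assert list(hits.columns) == tp.HIT_COLUMNS

    def test_duplicate_identifiers_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="duplicate"):
            tp.scan_transcriptome(
                {"a": "ACGUACGUACGUACGUACGUACG"},
                pd.Series(["ACGT" * 30, "ACGT" * 30], index=["t", "t"]),  # type: ignore[arg-type]
                "mRNA",
            )

    def test_junction_spanning_site_needs_circular_mode(self, rng):
        m = syn._draw_mirna(rng)
        circ = syn.plant_junction_site(syn._random_dna(rng, 300), m, rng)
        linear = tp.scan_transcriptome({"m": m}, {"c": circ}, "circRNA", circular=False)
        circular = tp.scan_transcriptome({"m": m}, {"c": circ}, "circRNA", circular=True)
        assert len(linear) == 0
        assert len(circular) == 1
        assert bool(circular["junction_spanning"].iloc[0])
        # wrapped coordinates: the site ends before it starts on the linearization
        assert circular["site_end"].iloc[0] < circular["site_start"].iloc[0]

    def test_threshold_monotonicity(self, small_bundle):
        mirnas = small_bundle.sequences["miRNA"]
        transcripts = small_bundle.sequences["mRNA"]

        def hit_set(s_min, g_max):
            df = tp.scan_transcriptome(mirnas, transcripts, "mRNA", s_min=s_min, g_max=g_max)
            return {(r.mirna_id, r.transcript_id, r.site_start) for r in df.itertuples()}

        base = hit_set(140.0, -25.0)
        assert hit_set(150.0, -25.0) <= base
        assert hit_set(140.0, -35.0) <= base
        assert hit_set(155.0, -35.0) <= base

    def test_reverse_complement_does_not_preserve_hits(self, rng):
        # orientation guard: only antisense complementarity may score
        m = syn._draw_mirna(rng)
        site = syn._dna_site_for(m)
        host = syn._random_dna(rng, 100) + site + syn._random_dna(rng, 100)
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        host_rc = "".join(comp[b] for b in reversed(host))
        assert len(tp.scan_transcriptome({"m": m}, {"t": host}, "mRNA")) == 1
        assert len(tp.scan_transcriptome({"m": m}, {"t": host_rc}, "mRNA")) == 0

    def test_planted_site_recall_is_total(self, small_bundle):
        mirnas = small_bundle.sequences["miRNA"]
        found = set()
        for cls in ("mRNA", "lncRNA", "circRNA"):
            hits = tp.scan_transcriptome(
                mirnas, small_bundle.sequences[cls], cls, circular=(cls == "circRNA")
            )
            found |= {(r.mirna_id, r.transcript_id, r.transcript_class) for r in hits.itertuples()}
        assert set(small_bundle.truth.true_targets) <= found
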