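"""Miranda-style miRNA target prediction.

A candidate site must (1) pair the miRNA seed (positions 2-8 from the 5' end)
with strict Watson-Crick complementarity — no G:U wobble, (2) reach an alignment
score S >= S_min under the published Miranda default weights (match +5, G:U
wobble +1, mismatch -3, gap open -9, gap extend -4, with substitution scores
doubled at miRNA positions 2-8), and (3) have a duplex free energy
dG <= G_max kcal/mol under a nearest-neighbor stacking model. Defaults
S_min = 150, G_max = -30.

Sequences are DNA on disk and RNA internally (T->U at entry). Coordinates are
1-based inclusive on the transcript's 5'->3' strand. circRNA transcripts can be
scanned circularly: the scan window is wrapped past the backsplice junction
(located between the last and first nucleotide of the linearized record) and
junction-spanning sites are reported once, with wrapped coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

MATCH_SCORE = 5.0
WOBBLE_SCORE = 1.0
MISMATCH_SCORE = -3.0
GAP_OPEN = -9.0
GAP_EXTEND = -4.0
#: miRNA seed positions (1-based, 5'->3', inclusive); substitution scores doubled here
SEED_START, SEED_END = 2, 8

S_MIN_DEFAULT = 150.0
G_MAX_DEFAULT = -30.0

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

#: duplex initiation penalty, kcal/mol
INITIATION_DG = 4.09
#: free-energy penalty per unpaired base internal to the duplex, kcal/mol
UNPAIRED_DG = 0.5
#: flat stack energy when one of the two pairs is a G:U wobble, kcal/mol
WOBBLE_STACK_DG = -1.0

# Watson-Crick nearest-neighbor stack free energies (Turner-style dG37,
# kcal/mol), keyed by (top 5'->3' dinucleotide, bottom 3'->5' dinucleotide);
# the ten unique parameters, expanded by 180-degree rotational symmetry below.
_STACK_CANONICAL = {
    ("AA", "UU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CU", "GA"): -2.08,
    ("CA", "GU"): -2.11,
    ("GU", "CA"): -2.24,
    ("GA", "CU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
}
STACK_ENERGIES: dict[tuple[str, str], float] = {}
for (_top, _bot), _dg in _STACK_CANONICAL.items():
    STACK_ENERGIES[(_top, _bot)] = _dg
    # rotating the duplex: 5'WX3'/3'YZ5' == 5'ZY3'/3'XW5'
    STACK_ENERGIES[(_bot[::-1], _top[::-1])] = _dg


def to_rna(seq: str) -> str:
    """Uppercase and map DNA T to RNA U; reject non-AUCG symbols."""
    rna = seq.upper().replace("T", "U")
    bad = set(rna) - set("AUCG")
    if bad:
        raise ValueError(f"non-AUCG symbols after U/T mapping: {sorted(bad)}")
    return rna


def revcomp_rna(seq: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[b] for b in reversed(seq))


def _is_wc(a: str, b: str) -> bool:
    return (a, b) in _WC


def _is_pair(a: str, b: str) -> bool:
    return (a, b) in _WC or (a, b) in _WOBBLE


def seed_match(mirna: str, window: str) -> bool:
    """Strict seed pairing: miRNA positions 2-8 Watson-Crick-complementary
    (no G:U) to the aligned window read 3'->5'.

    The window is the target site region, given 5'->3', assumed aligned
    antiparallel and ungapped to the miRNA: miRNA position i pairs window
    position len(window)-i+1 (1-based).
    """
    m = to_rna(mirna)
    w = to_rna(window)
    if len(m) < SEED_END:
        raise ValueError(f"miRNA shorter than {SEED_END} nt")
    if len(w) < SEED_END:
        return False
    for i in range(SEED_START - 1, SEED_END):  # 0-based miRNA index
        if not _is_wc(m[i], w[len(w) - 1 - i]):
            return False
    return True


def _sub_score(m_base: str, s_base: str, m_pos0: int) -> float:
    """Substitution score for miRNA base (0-based position) vs site base."""
    if _is_wc(m_base, s_base):
        s = MATCH_SCORE
    elif (m_base, s_base) in _WOBBLE:
        s = WOBBLE_SCORE
    else:
        s = MISMATCH_SCORE
    if SEED_START - 1 <= m_pos0 <= SEED_END - 1:
        s *= 2.0
    return s


@dataclass
class Alignment:
    """A local antiparallel alignment of a miRNA against a site.

    ``columns`` holds (mirna_pos0, site_pos0, kind) with kind one of
    'pair' (WC or wobble), 'mismatch', 'gap_mirna' (site base unpaired),
    'gap_site' (miRNA base unpaired). site_pos0 indexes the site 5'->3'.
    """

    score: float
    columns: list[tuple[int | None, int | None, str]]


def align_mirna_site(mirna: str, site: str) -> Alignment:
    """Best local (Smith-Waterman, affine-gap) alignment of the miRNA read
    5'->3' against the site read 3'->5' (antiparallel duplex)."""
    m = to_rna(mirna)
    s_fwd = to_rna(site)
    if not s_fwd:
        raise ValueError("empty site")
    y = s_fwd[::-1]  # site 3'->5'
    nm, ny = len(m), len(y)
    NEG = float("-inf")
    # three-state affine SW: M = aligned column, X = gap in site (miRNA base
    # unpaired), Y = gap in miRNA (site base unpaired)
    M = [[0.0] * (ny + 1) for _ in range(nm + 1)]
    X = [[NEG] * (ny + 1) for _ in range(nm + 1)]
    Y = [[NEG] * (ny + 1) for _ in range(nm + 1)]
    ptr: dict[tuple[str, int, int], tuple[str, int, int, str] | None] = {}
    best, best_cell = 0.0, None
    for i in range(1, nm + 1):
        for j in range(1, ny + 1):
            sub = _sub_score(m[i - 1], y[j - 1], i - 1)
            prev_best, prev_state = M[i - 1][j - 1], "M"
            if X[i - 1][j - 1] > prev_best:
                prev_best, prev_state = X[i - 1][j - 1], "X"
            if Y[i - 1][j - 1] > prev_best:
                prev_best, prev_state = Y[i - 1][j - 1], "Y"
            val = prev_best + sub
            if val >= 0:
                M[i][j] = val
                ptr[("M", i, j)] = (prev_state, i - 1, j - 1, "sub") if prev_best > 0 else None
            else:
                M[i][j] = 0.0
                ptr[("M", i, j)] = None
            x_open = M[i - 1][j] + GAP_OPEN
            x_ext = X[i - 1][j] + GAP_EXTEND
            if x_open >= x_ext:
                X[i][j] = x_open
                ptr[("X", i, j)] = ("M", i - 1, j, "gap_site")
            else:
                X[i][j] = x_ext
                ptr[("X", i, j)] = ("X", i - 1, j, "gap_site")
            y_open = M[i][j - 1] + GAP_OPEN
            y_ext = Y[i][j - 1] + GAP_EXTEND
            if y_open >= y_ext:
                Y[i][j] = y_open
                ptr[("Y", i, j)] = ("M", i, j - 1, "gap_mirna")
            else:
                Y[i][j] = y_ext
                ptr[("Y", i, j)] = ("Y", i, j - 1, "gap_mirna")
            if M[i][j] > best:
                best, best_cell = M[i][j], ("M", i, j)

    columns: list[tuple[int | None, int | None, str]] = []
    if best_cell is not None:
        state, i, j = best_cell
        while True:
            if state == "M":
                a, b = m[i - 1], y[j - 1]
                kind = "pair" if _is_pair(a, b) else "mismatch"
                # map the reversed-site index back to 5'->3' coordinates
                columns.append((i - 1, ny - j, kind))
            elif state == "X":
                columns.append((i - 1, None, "gap_site"))
            else:
                columns.append((None, ny - j, "gap_mirna"))
            nxt = ptr.get((state, i, j))
            if nxt is None:
                break
            state, i, j = nxt[0], nxt[1], nxt[2]
        columns.reverse()
    return Alignment(score=best, columns=columns)


def align_score(mirna: str, site: str) -> float:
    """Maximum local alignment score S of the antiparallel miRNA:site duplex."""
    return align_mirna_site(mirna, site).score


def duplex_energy(mirna: str, site: str) -> float:
    """Nearest-neighbor stacking free energy (kcal/mol) of the best duplex.

    Sum of stack energies over consecutive paired columns adjacent in both
    strands, plus the duplex initiation penalty, plus a fixed penalty per base
    left unpaired between the first and last paired column. More pairing gives
    a lower (more negative) dG; zero stacks leave only the initiation penalty.
    """
    aln = align_mirna_site(mirna, site)
    return alignment_energy(to_rna(mirna), to_rna(site), aln)


def alignment_energy(m_rna: str, site_rna: str, aln: Alignment) -> float:
    paired = [(i, j) for i, j, kind in aln.columns if kind == "pair"]
    if not paired:
        return INITIATION_DG
    dg = INITIATION_DG
    for (i1, j1), (i2, j2) in zip(paired, paired[1:]):
        if i2 == i1 + 1 and j2 == j1 - 1:  # adjacent in both strands (antiparallel)
            top = m_rna[i1] + m_rna[i2]
            bot = site_rna[j1] + site_rna[j2]  # bottom strand read 3'->5' under top
            if (top, bot) in STACK_ENERGIES:
                dg += STACK_ENERGIES[(top, bot)]
            else:
                dg += WOBBLE_STACK_DG
    # unpaired bases strictly inside the duplex span
    first = aln.columns.index((paired[0][0], paired[0][1], "pair"))
    last = len(aln.columns) - 1 - aln.columns[::-1].index((paired[-1][0], paired[-1][1], "pair"))
    n_unpaired = sum(1 for c in aln.columns[first : last + 1] if c[2] != "pair")
    return dg + UNPAIRED_DG * n_unpaired


# ---------------------------------------------------------------------------
# transcriptome scanning
# ---------------------------------------------------------------------------

#: extra target nucleotides 5' of the seed-paired region offered to the aligner
SCAN_SLACK = 7


def _window_length(mirna_len: int) -> int:
    return mirna_len + SCAN_SLACK


def scan_pair(
    mirna_id: str,
    mirna_seq: str,
    transcript_id: str,
    transcript_seq: str,
    transcript_class: str,
    s_min: float = S_MIN_DEFAULT,
    g_max: float = G_MAX_DEFAULT,
    circular: bool = False,
) -> list[dict]:
    """All passing, non-overlapping sites of one miRNA on one transcript."""
    m = to_rna(mirna_seq)
    t = to_rna(transcript_seq)
    n = len(t)
    if n == 0 or len(m) < SEED_END:
        return []
    lw = _window_length(len(m))
    # circular transcripts are padded on both sides with wrap-around context so
    # junction-spanning duplexes align with their full upstream/downstream site
    pad = min(lw - 1, n) if circular else 0
    scan_seq = t[n - pad :] + t + t[:pad] if circular else t
    seed_rc = revcomp_rna(m[SEED_START - 1 : SEED_END])  # 7-mer on the target
    seed_len = SEED_END - SEED_START + 1
    raw_hits: list[dict] = []
    # seed block start positions covering each original coordinate exactly once
    for q in range(pad, pad + n):
        if q + seed_len + (SEED_START - 1) > len(scan_seq):
            break
        if scan_seq[q : q + seed_len] != seed_rc:
            continue
        # target position pairing miRNA position 1 sits 3' of the seed block
        e = q + seed_len + (SEED_START - 1)  # exclusive end of the site window
        s = max(0, e - lw)
        site = scan_seq[s:e]
        aln = align_mirna_site(m, site)
        if aln.score < s_min:
            continue
        dg = alignment_energy(m, to_rna(site), aln)
        if dg > g_max:
            continue
        site_positions = [j for _, j, kind in aln.columns if j is not None]
        if not site_positions:
            continue
        start0 = s + min(site_positions) - pad  # may wrap below 0 / above n
        end0 = s + max(site_positions) - pad
        spans_junction = circular and (start0 < 0 or end0 >= n)
        raw_hits.append(
            {
                "mirna_id": mirna_id,
                "transcript_id": transcript_id,
                "transcript_class": transcript_class,
                "site_start": start0 % n + 1,
                "site_end": end0 % n + 1,
                "linear_start": start0,
                "linear_end": end0,
                "score_S": aln.score,
                "delta_G": dg,
                "seed_matched": True,
                "junction_spanning": bool(spans_junction),
            }
        )
    return _collapse_overlaps(raw_hits)


def _collapse_overlaps(hits: list[dict]) -> list[dict]:
    """Keep the best-S site per non-overlapping region (ties: leftmost start)."""
    ranked = sorted(hits, key=lambda h: (-h["score_S"], h["linear_start"]))
    kept: list[dict] = []
    for h in ranked:
        if all(
            h["linear_end"] < k["linear_start"] or h["linear_start"] > k["linear_end"]
            for k in kept
        ):
            kept.append(h)
    kept.sort(key=lambda h: h["linear_start"])
    for h in kept:
        del h["linear_start"], h["linear_end"]
    return kept


HIT_COLUMNS = [
    "mirna_id",
    "transcript_id",
    "transcript_class",
    "site_start",
    "site_end",
    "score_S",
    "delta_G",
    "seed_matched",
    "junction_spanning",
]


def scan_transcriptome(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    transcript_class: str,
    s_min: float = S_MIN_DEFAULT,
    g_max: float = G_MAX_DEFAULT,
    circular: bool = False,
) -> pd.DataFrame:
    """Scan every miRNA against every transcript; one row per passing site.

    ``circular=True`` treats each transcript as covalently closed (circRNA):
    the scan wraps past the backsplice junction between the record's last and
    first nucleotide.
    """
    if len(set(mirnas)) != len(mirnas) or len(set(transcripts)) != len(transcripts):
        raise ValueError("duplicate identifiers")
    rows: list[dict] = []
    for t_id in transcripts:
        for m_id in mirnas:
            rows.extend(
                scan_pair(
                    m_id,
                    mirnas[m_id],
                    t_id,
                    transcripts[t_id],
                    transcript_class,
                    s_min=s_min,
                    g_max=g_max,
                    circular=circular,
                )
            )
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return df.sort_values(
        ["mirna_id", "transcript_id", "site_start"], kind="mergesort"
    ).reset_index(drop=True)
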