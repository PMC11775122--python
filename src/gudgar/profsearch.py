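"""Profile-based homology search: PSSM construction, local alignment, E-values.

A gene family's seed alignment is turned into a position-specific scoring
matrix (log-odds in nats against a fixed amino-acid background).  Proteomes
are scored by Smith-Waterman local alignment of each protein against the
profile columns with affine gap penalties, and raw scores are converted to
E-values through a Gumbel null fitted to shuffled (i.i.d. background)
sequences, following the extreme-value statistics of ungapped local
alignment scores:

    E = K * m * N * exp(-lambda * S)

with m the profile length and N the searched proteome size in residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from gudgar.iohub import AMINO_ACIDS, PROTEIN_ALPHABET
from gudgar.synthgen import BACKGROUND_FREQS

_AA_INDEX = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}
_EULER_GAMMA = 0.5772156649015329
SCORE_FLOOR = -20.0  # cap for log-odds of unseen residues at pseudocount weight 0


@dataclass
class ProfileModel:
    """Position-specific scoring model plus its fitted Gumbel null."""

    family_id: str
    length: int
    log_odds: np.ndarray  # length x 21 (20 aa + X), nats; X column all zeros
    background_freqs: np.ndarray  # 20-vector summing to 1
    modal_residues: str  # per-column modal seed residue (identity reference)
    mean_seed_length: int
    gap_open: float = -11.0
    gap_extend: float = -1.0
    null_lambda: float = float("nan")
    null_K: float = float("nan")
    null_n: int = 0

    def __post_init__(self) -> None:
        if abs(float(self.background_freqs.sum()) - 1.0) > 1e-9:
            raise ValueError("background_freqs must sum to 1")
        if self.log_odds.shape != (self.length, 21):
            raise ValueError("log_odds must be length x 21")

    @property
    def calibrated(self) -> bool:
        return self.null_n > 0 and self.null_lambda > 0


@dataclass(frozen=True)
class HomologyHit:
    genome_id: str
    locus_tag: str
    family_id: str
    raw_score: float
    e_value: float
    percent_identity: float
    query_span: tuple[int, int]  # 1-based inclusive residue range, (0, 0) if empty
    profile_span: tuple[int, int]


# ---------------------------------------------------------------------------
# model building


def build_pssm(
    seed_alignment: Sequence[tuple[str, str]],
    pseudocount_weight: float = 1.0,
    family_id: str = "family",
    background: np.ndarray | None = None,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> ProfileModel:
    """Build a PSSM from an aligned seed family.

    Columns with more than 50% gaps are dropped.  Per-column frequencies get
    background-proportional pseudocounts with weight alpha:
    f'(a) = (c(a) + alpha*bg(a)) / (n + alpha); log-odds = ln(f'/bg).
    The ambiguity residue X scores 0 at every position.
    """
    if not seed_alignment:
        raise ValueError("empty seed alignment")
    seqs = [s.upper() for _, s in seed_alignment]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("seed sequences have unequal lengths")
    bg = BACKGROUND_FREQS if background is None else np.asarray(background, dtype=float)
    bg = bg / bg.sum()

    keep_cols = [
        c for c in range(L) if sum(s[c] == "-" for s in seqs) <= 0.5 * len(seqs)
    ]
    if not keep_cols:
        raise ValueError("all columns exceed the 50% gap threshold")

    alpha = pseudocount_weight
    log_odds = np.zeros((len(keep_cols), 21))
    modal = []
    for out_i, c in enumerate(keep_cols):
        counts = np.zeros(20)
        for s in seqs:
            j = AMINO_ACIDS.find(s[c])
            if j >= 0:
                counts[j] += 1
        n = counts.sum()
        freqs = (counts + alpha * bg) / (n + alpha) if (n + alpha) > 0 else bg
        with np.errstate(divide="ignore"):
            scores = np.log(freqs / bg)
        scores[np.isneginf(scores)] = SCORE_FLOOR
        log_odds[out_i, :20] = np.maximum(scores, SCORE_FLOOR)
        best = int(np.argmax(counts)) if n > 0 else 0
        # tie-break to the alphabetically first modal residue
        best = min(np.flatnonzero(counts == counts[best])) if n > 0 else 0
        modal.append(AMINO_ACIDS[best])

    mean_len = int(round(np.mean([sum(ch != "-" for ch in s) for s in seqs])))
    return ProfileModel(
        family_id=family_id,
        length=len(keep_cols),
        log_odds=log_odds,
        background_freqs=bg,
        modal_residues="".join(modal),
        mean_seed_length=max(mean_len, 1),
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


# ---------------------------------------------------------------------------
# local alignment

_TOL = 1e-9


try:  # score-only kernel; used for calibration and proteome-wide screening
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = lambda *a, **k: (lambda f: f)  # noqa: E731


@_njit(cache=True)
def _sw_scores(lod, qidx, qlens, go, ge):  # pragma: no cover - jit-compiled
    B = qidx.shape[0]
    L = lod.shape[0]
    out = np.zeros(B)
    for b in range(B):
        n = qlens[b]
        h_prev = np.zeros(n + 1)
        ix_prev = np.full(n + 1, -1e30)
        h_cur = np.zeros(n + 1)
        ix_cur = np.full(n + 1, -1e30)
        best = 0.0
        for i in range(L):
            iy = -1e30
            prev_h0 = 0.0
            for j in range(1, n + 1):
                m = h_prev[j - 1] + lod[i, qidx[b, j - 1]]
                if m < 0.0:
                    m = 0.0
                ix = h_prev[j] + go
                t = ix_prev[j] + ge
                if t > ix:
                    ix = t
                h0 = m if m > ix else ix
                if h0 < 0.0:
                    h0 = 0.0
                iy = iy + ge
                t = prev_h0 + go
                if t > iy:
                    iy = t
                h = h0 if h0 > iy else iy
                if h > best:
                    best = h
                h_cur[j] = h
                ix_cur[j] = ix
                prev_h0 = h0
            h_prev, h_cur = h_cur, h_prev
            ix_prev, ix_cur = ix_cur, ix_prev
        out[b] = best
    return out


def sw_score_batch(profile: ProfileModel, queries: Sequence[str]) -> np.ndarray:
    """Raw local-alignment scores of many queries against one profile.

    Same recurrence as :func:`sw_profile_align`, score only.
    """
    if not queries:
        return np.zeros(0)
    lens = np.array([len(q) for q in queries], dtype=np.int64)
    if (lens == 0).any():
        raise ValueError("empty query")
    maxlen = int(lens.max())
    qidx = np.full((len(queries), maxlen), 20, dtype=np.int64)  # pad with X (scores 0)
    for b, q in enumerate(queries):
        qidx[b, : len(q)] = [_AA_INDEX.get(ch, 20) for ch in q.upper()]
    return _sw_scores(
        np.ascontiguousarray(profile.log_odds),
        qidx,
        lens,
        float(profile.gap_open),
        float(profile.gap_extend),
    )


def sw_profile_align(
    profile: ProfileModel, query: str
) -> tuple[float, tuple[int, int, int, int], float]:
    """Smith-Waterman local alignment of *query* against the profile columns.

    Affine gaps: the first gap residue costs ``gap_open``, each additional one
    ``gap_extend`` (both negative, nats).  Returns
    (raw_score, (q_start, q_end, p_start, p_end), percent_identity) with
    1-based inclusive spans; a score of 0 yields the empty span (0, 0, 0, 0).
    Percent identity counts aligned columns where the query residue equals the
    column's modal seed residue, over aligned (non-gap) columns.

    Ties among equal-scoring cells resolve to the smallest (query_end,
    profile_end); traceback prefers diagonal over up (profile-consuming gap)
    over left (query-consuming gap).
    """
    query = query.upper()
    if not query:
        raise ValueError("empty query")
    L, n = profile.length, len(query)
    go, ge = profile.gap_open, profile.gap_extend
    qidx = np.array([_AA_INDEX.get(ch, 20) for ch in query])

    # Gotoh with open-from-H; the horizontal state Iy is computed as a
    # running-max scan, which vectorizes each row over the query axis.
    M = np.zeros((L + 1, n + 1))  # best score ending in a match at (i, j)
    Ix = np.full((L + 1, n + 1), -np.inf)  # gap in query (profile column unmatched)
    Iy = np.full((L + 1, n + 1), -np.inf)  # gap in profile (query residue unmatched)
    H = np.zeros((L + 1, n + 1))
    offs = np.arange(n) * ge  # helper for the horizontal-gap scan

    for i in range(1, L + 1):
        sub = profile.log_odds[i - 1][qidx]
        M[i, 1:] = np.maximum(H[i - 1, :-1] + sub, 0.0)
        Ix[i, 1:] = np.maximum(H[i - 1, 1:] + go, Ix[i - 1, 1:] + ge)
        h0 = np.maximum(np.maximum(M[i, 1:], Ix[i, 1:]), 0.0)
        # Iy[i, j] = max_{k<j} h0[k] + go + (j-1-k)*ge  (open never pays from Iy)
        scan = np.maximum.accumulate(np.concatenate(([-np.inf], h0[:-1])) - offs)
        Iy[i, 1:] = scan + offs + go
        H[i, 1:] = np.maximum(h0, Iy[i, 1:])

    best = float(H.max())
    if best <= 0.0:
        return 0.0, (0, 0, 0, 0), 0.0

    # smallest (query_end, profile_end) among maximal match cells (the optimum
    # always ends in a match because gap penalties are negative)
    ii, jj = np.nonzero(M >= best - 1e-12)
    j_end, i_end = min(zip(jj.tolist(), ii.tolist()))

    def resolve(i: int, j: int) -> str:
        if abs(H[i, j] - M[i, j]) <= _TOL:
            return "M"
        if abs(H[i, j] - Ix[i, j]) <= _TOL:
            return "Ix"
        return "Iy"

    i, j = i_end, j_end
    state = "M"
    matches = aligned = 0
    while i > 0 and j > 0:
        if state == "M":
            aligned += 1
            if query[j - 1] == profile.modal_residues[i - 1]:
                matches += 1
            i, j = i - 1, j - 1
            if H[i, j] <= _TOL:
                break
            state = resolve(i, j)
        elif state == "Ix":
            extended = abs(Ix[i, j] - (Ix[i - 1, j] + ge)) <= _TOL
            i -= 1
            if not extended:
                state = resolve(i, j)
                if H[i, j] <= _TOL:
                    break
        else:  # Iy
            extended = abs(Iy[i, j] - (Iy[i, j - 1] + ge)) <= _TOL
            j -= 1
            if not extended:
                state = "M" if abs(M[i, j] - max(M[i, j], Ix[i, j])) <= _TOL else "Ix"
                if H[i, j] <= _TOL:
                    break
    q_start, p_start = j + 1, i + 1
    pct = 100.0 * matches / aligned if aligned else 0.0
    return best, (q_start, j_end, p_start, i_end), pct


# ---------------------------------------------------------------------------
# E-value calibration


def calibrate_null(
    profile: ProfileModel, n_shuffles: int = 200, seed: int = 0
) -> tuple[float, float]:
    """Fit a Gumbel null to scores of i.i.d. background sequences.

    Method of moments: lambda = pi / (sigma * sqrt(6)); the location
    mu = mean - gamma/lambda, and K solves mu = ln(K*m*n)/lambda with m the
    profile length and n the shuffle length.  Sets ``null_lambda``/``null_K``
    on the profile and returns them.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    n = profile.mean_seed_length
    shuffles = [
        "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=n, p=profile.background_freqs))
        for _ in range(n_shuffles)
    ]
    scores = sw_score_batch(profile, shuffles)
    sigma = float(scores.std(ddof=1))
    if sigma <= 0:
        raise ValueError("zero variance in shuffle scores; cannot calibrate")
    lam = math.pi / (sigma * math.sqrt(6.0))
    mu = float(scores.mean()) - _EULER_GAMMA / lam
    K = math.exp(lam * mu) / (profile.length * n)
    profile.null_lambda = lam
    profile.null_K = K
    profile.null_n = n_shuffles
    return lam, K


def e_value(profile: ProfileModel, score: float, proteome_residues: int) -> float:
    """Expected false hits at *score* in a proteome of N residues."""
    if not profile.calibrated:
        raise ValueError(f"profile {profile.family_id!r} is not calibrated")
    return profile.null_K * profile.length * proteome_residues * math.exp(
        -profile.null_lambda * score
    )


# ---------------------------------------------------------------------------
# proteome search


def search_proteome(
    profiles: Iterable[ProfileModel],
    genome_proteins: dict[str, list[tuple[str, str]]],
    e_cutoff: float = 1e-10,
    per_family_cutoffs: dict[str, float] | None = None,
) -> list[HomologyHit]:
    """Score every (profile, protein) pair; keep hits with E <= cutoff.

    *genome_proteins* maps genome_id -> [(locus_tag, protein)].  E-values are
    computed against each genome's own proteome size.  Results are sorted by
    ascending E-value then locus_tag.
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be > 0")
    cutoffs = per_family_cutoffs or {}
    hits: list[HomologyHit] = []
    for genome_id, proteins in genome_proteins.items():
        if not proteins:
            continue
        N = sum(len(seq) for _, seq in proteins)
        seqs = [seq for _, seq in proteins]
        for prof in profiles:
            cutoff = cutoffs.get(prof.family_id, e_cutoff)
            scores = sw_score_batch(prof, seqs)
            for (locus, seq), screen_score in zip(proteins, scores):
                if screen_score <= 0 or e_value(prof, float(screen_score), N) > cutoff:
                    continue
                score, (qs, qe, ps, pe), pct = sw_profile_align(prof, seq)
                E = e_value(prof, score, N)
                if E <= cutoff:
                    hits.append(
                        HomologyHit(
                            genome_id=genome_id,
                            locus_tag=locus,
                            family_id=prof.family_id,
                            raw_score=score,
                            e_value=E,
                            percent_identity=pct,
                            query_span=(qs, qe),
                            profile_span=(ps, pe),
                        )
                    )
    hits.sort(key=lambda h: (h.e_value, h.locus_tag))
    return hits


# ---------------------------------------------------------------------------
# serialization


def write_profile(profile: ProfileModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# family_id\t{profile.family_id}\n")
        fh.write(f"# mean_seed_length\t{profile.mean_seed_length}\n")
        fh.write(f"# gap_open\t{profile.gap_open}\n")
        fh.write(f"# gap_extend\t{profile.gap_extend}\n")
        fh.write(f"# null_lambda\t{profile.null_lambda}\n")
        fh.write(f"# null_K\t{profile.null_K}\n")
        fh.write(f"# null_n\t{profile.null_n}\n")
        fh.write(f"# modal_residues\t{profile.modal_residues}\n")
        fh.write("# background\t" + "\t".join(f"{x:.6g}" for x in profile.background_freqs) + "\n")
        fh.write("column\t" + "\t".join(PROTEIN_ALPHABET) + "\n")
        for i in range(profile.length):
            fh.write(
                f"{i + 1}\t" + "\t".join(f"{x:.6g}" for x in profile.log_odds[i]) + "\n"
            )


def read_profile(path: str | Path) -> ProfileModel:
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    bg: np.ndarray | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("# background\t"):
            bg = np.array([float(x) for x in line.split("\t")[1:]])
        elif line.startswith("# "):
            key, value = line[2:].split("\t", 1)
            meta[key] = value
        elif line and not line.startswith("column"):
            rows.append([float(x) for x in line.split("\t")[1:]])
    if bg is None or not rows:
        raise ValueError(f"malformed profile file {path}")
    return ProfileModel(
        family_id=meta["family_id"],
        length=len(rows),
        log_odds=np.array(rows),
        background_freqs=bg,
        modal_residues=meta["modal_residues"],
        mean_seed_length=int(meta["mean_seed_length"]),
        gap_open=float(meta["gap_open"]),
        gap_extend=float(meta["gap_extend"]),
        null_lambda=float(meta["null_lambda"]),
        null_K=float(meta["null_K"]),
        null_n=int(meta["null_n"]),
    )


def write_hits(hits: Sequence[HomologyHit], path: str | Path) -> None:
    cols = "genome_id locus_tag family_id score e_value pct_identity q_start q_end p_start p_end".split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.genome_id,
                        h.locus_tag,
                        h.family_id,
                        f"{h.raw_score:.6g}",
                        f"{h.e_value:.6g}",
                        f"{h.percent_identity:.2f}",
                        str(h.query_span[0]),
                        str(h.query_span[1]),
                        str(h.profile_span[0]),
                        str(h.profile_span[1]),
                    ]
                )
                + "\n"
            )
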