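"""Methylation-aware transcription-factor motif analysis.

A PWM is a position probability matrix over A,C,G,T with a background
distribution.  Scores are log-odds in bits.  P-values are exact under the
background model: per-position score contributions are discretized on a fixed
grid (default 1e-3 bits) and the full score distribution is built by
positionwise convolution, so the tail probability of any observed score is
queryable without Monte Carlo.  Scanning considers both strands; similarity
between PWMs is the best ungapped local alignment of columns scored by
per-column Pearson correlation; motif trees come from UPGMA.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

PROB_FLOOR = 1e-4  # zero probabilities floored before log-odds


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


@dataclasses.dataclass
class PWM:
    """Position probability matrix (w x 4, columns ordered A,C,G,T)."""

    name: str
    probs: np.ndarray
    background: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"PWM {self.name!r}: matrix must be w x 4 with w >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name!r}: position probabilities must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name!r}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """w x 4 log2(p/bg) matrix with zero probabilities floored."""
        p = np.maximum(self.probs, PROB_FLOOR)
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background)

    def reverse_complement(self) -> "PWM":
        # reversed columns with complemented rows: A<->T, C<->G
        probs = self.probs[::-1, [3, 2, 1, 0]]
        bg = self.background[[3, 2, 1, 0]]
        return PWM(self.name + "_rc", probs, bg)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def sample_site(self, rng: np.random.Generator) -> str:
        """Sample a site base-by-base from the position probabilities."""
        return "".join(
            BASES[rng.choice(4, p=row / row.sum())] for row in self.probs)


# ---------------------------------------------------------------------------
# Exact score distribution under the background model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ScoreDistribution:
    """Exact distribution of discretized log-odds scores under background.

    Scores are integers on a grid of ``grid`` bits; ``pmf[k]`` is the
    probability of integer score ``offset + k``.
    """

    int_scores: np.ndarray  # w x 4 integer per-position contributions
    pmf: np.ndarray
    offset: int
    grid: float

    def score_word(self, word: str) -> float:
        """Discretized log-odds score of a length-w word, in bits."""
        idx = [_BASE_INDEX[b] for b in word.upper()]
        return int(self.int_scores[np.arange(len(idx)), idx].sum()) * self.grid

    def p_value(self, score_bits: float) -> float:
        """P(score >= observed) under the background model."""
        k = int(round(score_bits / self.grid)) - self.offset
        if k <= 0:
            return 1.0
        if k >= len(self.pmf):
            return 0.0
        return float(self.pmf[k:].sum())

    def score_threshold(self, p_threshold: float) -> float:
        """Smallest grid score whose tail probability is <= ``p_threshold``."""
        tail = np.cumsum(self.pmf[::-1])[::-1]
        ok = np.nonzero(tail <= p_threshold)[0]
        if len(ok) == 0:
            return np.inf
        return (self.offset + ok[0]) * self.grid


def score_distribution(pwm: PWM, grid: float = 1e-3) -> ScoreDistribution:
    """Build the exact score distribution by positionwise convolution."""
    lo = pwm.log_odds()
    int_scores = np.round(lo / grid).astype(np.int64)
    mins = int_scores.min(axis=1)
    maxs = int_scores.max(axis=1)
    offset = int(mins.sum())
    size = int((maxs - mins).sum()) + 1
    pmf = np.zeros(size)
    pmf[0] = 1.0
    used = 1  # occupied prefix length, grows per position
    bg = pwm.background
    for i in range(pwm.width):
        span = int(maxs[i] - mins[i])
        new = np.zeros(used + span)
        for b in range(4):
            shift = int(int_scores[i, b] - mins[i])
            new[shift:shift + used] += bg[b] * pmf[:used]
        used += span
        pmf = new
    return ScoreDistribution(int_scores=int_scores, pmf=pmf,
                             offset=offset, grid=grid)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MotifHit:
    seq_id: str
    offset: int           # 0-based offset of the site start in the sequence
    strand: str           # '+' or '-'
    score: float          # log-odds, bits (discretized grid)
    p_value: float
    motif: str


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        code[arr == ord(b)] = i
    return code


def _window_int_scores(code: np.ndarray, int_scores: np.ndarray) -> np.ndarray:
    """Integer score of every window; windows containing non-ACGT get -inf."""
    w = int_scores.shape[0]
    n = len(code) - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for i in range(w):
        c = code[i:i + n]
        ok = c >= 0
        valid &= ok
        scores += np.where(ok, int_scores[i, np.clip(c, 0, 3)], 0)
    scores[~valid] = -np.inf
    return scores


def scan(sequence: str, pwm: PWM, p_threshold: float = 1e-4,
         seq_id: str = "seq", dist: ScoreDistribution | None = None,
         both_strands: bool = True) -> list[MotifHit]:
    """Scan a sequence for motif occurrences with exact p <= threshold.

    Both strands are scanned; a reverse-strand hit at offset ``o`` means the
    reverse complement of ``sequence[o:o+w]`` matches the motif.  Sequences
    shorter than the motif yield no hits.
    """
    if dist is None:
        dist = score_distribution(pwm)
    w = pwm.width
    if len(sequence) < w:
        return []
    code = _encode(sequence)
    hits: list[MotifHit] = []
    strands = [("+", dist.int_scores)]
    if both_strands:
        rc = pwm.reverse_complement()
        # same background distribution assumed symmetric enough to share the
        # score distribution only when bg is complement-symmetric; rebuild if not
        rc_dist = score_distribution(rc, grid=dist.grid)
        strands.append(("-", rc_dist.int_scores))
    thr = dist.score_threshold(p_threshold)
    for strand, int_scores in strands:
        win = _window_int_scores(code, int_scores)
        sel = np.nonzero(win * dist.grid >= thr - 1e-12)[0]
        for o in sel:
            s = float(win[o] * dist.grid)
            hits.append(MotifHit(seq_id=seq_id, offset=int(o), strand=strand,
                                 score=s, p_value=dist.p_value(s),
                                 motif=pwm.name))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(h) for h in hits],
        columns=["seq_id", "offset", "strand", "score", "p_value", "motif"])


# ---------------------------------------------------------------------------
# Enrichment against background windows
# ---------------------------------------------------------------------------

def _best_scores(windows: dict[str, str], pwm: PWM,
                 dist: ScoreDistribution) -> pd.Series:
    """Best (max over offsets and strands) log-odds score per sequence."""
    rc_int = score_distribution(pwm.reverse_complement(), dist.grid).int_scores
    out = {}
    for sid, seq in windows.items():
        if len(seq) < pwm.width:
            continue
        code = _encode(seq)
        fwd = _window_int_scores(code, dist.int_scores)
        rev = _window_int_scores(code, rc_int)
        best = max(fwd.max(initial=-np.inf), rev.max(initial=-np.inf))
        if np.isfinite(best):
            out[sid] = best * dist.grid
    return pd.Series(out, dtype=float)


def motif_enrichment(foreground: dict[str, str], background: dict[str, str],
                     pwms: Sequence[PWM], p_cutoff: float = 1e-3,
                     n_resamples: int = 1000,
                     seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Test each PWM for enrichment in foreground vs background windows.

    The group statistic is the mean over foreground sequences of the best
    per-sequence log-odds score; the null re-draws size-matched sets from the
    background windows.  Empirical p = (1 + #{null >= observed}) / (1 + R).
    """
    if not foreground:
        raise ValueError("empty foreground window set")
    if not background:
        raise ValueError("empty background window set")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rows = []
    for pwm in pwms:
        dist = score_distribution(pwm)
        fg = _best_scores(foreground, pwm, dist)
        bg = _best_scores(background, pwm, dist)
        if fg.empty or bg.empty:
            continue
        obs = fg.mean()
        size = len(fg)
        bg_vals = bg.to_numpy()
        replace = size > len(bg_vals)
        null = np.empty(n_resamples)
        for r in range(n_resamples):
            draw = rng.choice(bg_vals, size=size, replace=replace)
            null[r] = draw.mean()
        p = (1 + int((null >= obs).sum())) / (1 + n_resamples)
        rows.append({"motif": pwm.name, "statistic": obs,
                     "null_mean": null.mean(), "p_value": p,
                     "enriched": p <= p_cutoff})
    return pd.DataFrame(rows, columns=["motif", "statistic", "null_mean",
                                       "p_value", "enriched"])


# ---------------------------------------------------------------------------
# Intersection of hits with methylation sites
# ---------------------------------------------------------------------------

def intersect_hits_with_dms(hits: Sequence[MotifHit],
                            window_origin: dict[str, tuple[str, int]],
                            dms_positions: dict[str, tuple[str, int]],
                            width_by_motif: dict[str, int]) -> list[MotifHit]:
    """Keep hits whose genomic span covers any methylation site.

    ``window_origin`` maps a sequence ID to the (chrom, genomic start) of the
    extracted window, so intersection happens in genomic, not window,
    coordinates (clipped windows keep their true origin).
    """
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in dms_positions.values():
        by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    by_chrom = {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}
    kept = []
    for h in hits:
        chrom, origin = window_origin[h.seq_id]
        start = origin + h.offset
        end = start + width_by_motif[h.motif]
        positions = by_chrom.get(chrom)
        if positions is None:
            continue
        i = np.searchsorted(positions, start, side="left")
        if i < len(positions) and positions[i] < end:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# PWM similarity and UPGMA clustering
# ---------------------------------------------------------------------------

def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two 4-vectors; constant columns compare by
    identity (1 if equal, else 0)."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def pwm_similarity(pwm_a: PWM, pwm_b: PWM,
                   min_overlap: int = 4) -> tuple[float, int, str]:
    """Best ungapped local alignment of PWM columns.

    Returns ``(similarity, offset, orientation)`` where similarity is the mean
    per-column Pearson correlation over the best overlap (minimum overlap 4
    columns, or the shorter motif if narrower), offset is the position of
    ``pwm_b``'s first column relative to ``pwm_a``'s, and orientation is
    ``"forward"`` or ``"reverse"`` (reverse complement of ``pwm_b``).
    """
    wa, wb = pwm_a.width, pwm_b.width
    mo = min(min_overlap, wa, wb)
    best = (-np.inf, 0, "forward")
    for orientation, mb in (("forward", pwm_b.probs),
                            ("reverse", pwm_b.reverse_complement().probs)):
        for off in range(-(wb - mo), wa - mo + 1):
            a_lo, a_hi = max(0, off), min(wa, off + wb)
            if a_hi - a_lo < mo:
                continue
            cols = [_column_corr(pwm_a.probs[i], mb[i - off])
                    for i in range(a_lo, a_hi)]
            sim = float(np.mean(cols))
            if sim > best[0] + 1e-12:
                best = (sim, off, orientation)
    return best


def pwm_distance_matrix(pwms: Sequence[PWM]) -> pd.DataFrame:
    """Symmetric distance matrix, distance = 1 - best alignment similarity."""
    n = len(pwms)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim, _, _ = pwm_similarity(pwms[i], pwms[j])
            d[i, j] = d[j, i] = 1.0 - sim
    names = [p.name for p in pwms]
    return pd.DataFrame(d, index=names, columns=names)


@dataclasses.dataclass
class TreeNode:
    """Node of a rooted UPGMA tree; height is the merge height."""

    name: str
    height: float = 0.0
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [l for c in self.children for l in c.leaves()]

    def newick(self) -> str:
        return self._newick(parent_height=None) + ";"

    def _newick(self, parent_height: float | None) -> str:
        if self.is_leaf:
            label = self.name
        else:
            inner = ",".join(c._newick(self.height) for c in self.children)
            label = f"({inner})"
        if parent_height is None:
            return label
        return f"{label}:{parent_height - self.height:g}"


def upgma(distance: pd.DataFrame) -> TreeNode:
    """Average-linkage agglomeration with lexicographic tie-breaking.

    Cluster-pair distances are membership-size weighted averages (classic
    UPGMA); merge heights are half the merge distance and non-decreasing.
    """
    labels = list(distance.index)
    if len(labels) == 1:
        return TreeNode(name=labels[0])
    nodes: dict[str, TreeNode] = {l: TreeNode(name=l) for l in labels}
    sizes: dict[str, int] = {l: 1 for l in labels}
    d: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d[frozenset((a, b))] = float(distance.loc[a, b])
    active = sorted(labels)
    while len(active) > 1:
        best_pair, best_dist = None, np.inf
        for a, b in itertools.combinations(active, 2):
            dist_ab = d[frozenset((a, b))]
            if dist_ab < best_dist - 1e-15:
                best_pair, best_dist = (a, b), dist_ab
        a, b = best_pair  # type: ignore[misc]
        new_name = f"({a}+{b})"
        height = best_dist / 2.0
        nodes[new_name] = TreeNode(name=new_name, height=height,
                                   children=(nodes[a], nodes[b]))
        sizes[new_name] = sizes[a] + sizes[b]
        for c in active:
            if c in (a, b):
                continue
            da = d.pop(frozenset((a, c)))
            db = d.pop(frozenset((b, c)))
            d[frozenset((new_name, c))] = (
                (sizes[a] * da + sizes[b] * db) / (sizes[a] + sizes[b]))
        d.pop(frozenset((a, b)))
        active = sorted([c for c in active if c not in (a, b)] + [new_name])
    return nodes[active[0]]


# ---------------------------------------------------------------------------
# Window extraction around methylation sites
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Window:
    site_id: str
    chrom: str
    start: int   # genomic start of the extracted window
    seq: str
    clipped: bool
    has_n: bool


def extract_windows(sites: pd.DataFrame, genome: dict[str, str],
                    flank: int = 20) -> dict[str, Window]:
    """Extract the sequence around each site (site +/- ``flank`` bp, so 41 bp
    by default); windows hitting a chromosome end are clipped and flagged.

    ``sites`` needs columns ``chrom`` and ``pos`` indexed by site ID.
    """
    out: dict[str, Window] = {}
    for site_id, row in sites.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        if chrom not in genome:
            raise KeyError(f"site {site_id!r}: unknown chromosome {chrom!r}")
        seq = genome[chrom]
        start = max(0, pos - flank)
        end = min(len(seq), pos + flank + 1)
        sub = seq[start:end].upper()
        out[str(site_id)] = Window(
            site_id=str(site_id), chrom=chrom, start=start, seq=sub,
            clipped=(end - start) < 2 * flank + 1,
            has_n=any(b not in _BASE_INDEX for b in sub))
    return out
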