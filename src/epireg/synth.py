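"""Synthetic multi-omics study generator with planted ground truth.

Emulates, at reduced scale, a cancer/normal cohort carrying three omics
layers — mRNA expression (log-normal, RPKM-like), miRNA expression
(log-normal, reads-per-million-like) and DNA methylation beta-values
(Beta-distributed in (0,1)) — together with a toy genome (FASTA plus gene,
CpG-island and chromatin-state BED tracks), motif instances planted around
chosen methylation sites, a gene-description corpus with planted topic
clusters, and survival times with planted methylation effects.  Every planted
signal is recorded in a :class:`GroundTruth` object so each downstream stage
has a recoverable answer key.

All sampling is driven by a single seed: identical spec + seed gives
byte-identical outputs across process invocations.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenomicIntervalSet, OmicsMatrix
from .motifs import PWM

OMICS = ("mrna", "mirna", "meth")

CHROMATIN_STATES = (
    "active_promoter", "weak_promoter", "enhancer", "transcribed",
    "weak_transcribed", "polycomb_repressed", "heterochromatin", "quiescent",
)


class ParameterError(ValueError):
    """A cohort/genome specification that cannot be realized."""


# ---------------------------------------------------------------------------
# Specification and ground truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CohortSpec:
    """Study conditions for the synthetic cohort.

    ``effect_size`` is the standardized mean shift planted into informative
    expression features (in units of ``noise_sd`` on the log scale); the
    methylation shift defaults to ``0.11 * effect_size`` on the beta scale
    (about the same number of within-group standard deviations at the default
    concentration) and can be overridden with ``beta_shift``.
    """

    n_cancer: int = 80
    n_normal: int = 40
    p_mrna: int = 2020
    p_mirna: int = 2020
    p_meth: int = 2020
    k_informative: int = 20
    effect_size: float = 2.0
    beta_shift: float | None = None
    noise_sd: float = 1.0
    concentration: float = 20.0     # Beta-distribution concentration per site
    complete_fraction: float = 1 / 3
    n_regulated_targets: int = 30
    regulators_per_target: int = 3
    regulation_r: float = 0.9       # target Pearson r of planted regressions
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cancer", "n_normal", "p_mrna", "p_mirna", "p_meth",
                     "k_informative"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        for p in (self.p_mrna, self.p_mirna, self.p_meth):
            if self.k_informative > p:
                raise ParameterError("k_informative exceeds a feature count")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        shift = self.resolved_beta_shift()
        if not 0 <= shift < 0.5:
            raise ParameterError(
                f"beta shift {shift:.3f} pushes a group mean outside (0, 1)")

    def resolved_beta_shift(self) -> float:
        if self.beta_shift is not None:
            return self.beta_shift
        return 0.11 * self.effect_size


@dataclasses.dataclass
class GroundTruth:
    """Answer key for every planted signal in the synthetic study."""

    informative: dict[str, list[str]]          # omic -> feature IDs
    deg_direction: dict[str, str]              # mRNA -> "up"/"down" in cancer
    dms_label: dict[str, str]                  # site -> hyper/hypo/medium
    regulator_map: dict[str, list[tuple[str, float]]]  # target -> (driver, coef)
    nlp_cluster: dict[str, int] = dataclasses.field(default_factory=dict)
    survival_dms: list[str] = dataclasses.field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["regulator_map"] = {k: [tuple(x) for x in v]
                              for k, v in d["regulator_map"].items()}
        d["nlp_cluster"] = {k: int(v) for k, v in d["nlp_cluster"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _feature_ids(prefix: str, p: int) -> list[str]:
    width = len(str(p))
    return [f"{prefix}{i:0{width}d}" for i in range(p)]


def generate_cohort(spec: CohortSpec
                    ) -> tuple[dict[str, OmicsMatrix], pd.DataFrame, GroundTruth]:
    """Generate the three omics matrices, sample metadata and ground truth.

    A ``complete_fraction`` of samples carries all three omics (those are the
    feature-selection cohort); the rest miss at least one omic and serve as
    held-out validation samples.  Expression is log-normal with planted
    group-mean shifts on the log scale; methylation is Beta-distributed with
    planted mean shifts, always inside (0, 1).  Zero-variance features are
    regenerated so none are emitted.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cancer + spec.n_normal
    samples = [f"S{i:04d}" for i in range(n)]
    group = np.array(["cancer"] * spec.n_cancer + ["normal"] * spec.n_normal)

    # sample completeness: complete samples carry all omics, the rest drop >= 1
    n_complete = max(1, int(round(spec.complete_fraction * n)))
    complete_idx = np.zeros(n, dtype=bool)
    # keep both classes represented among complete samples
    order = rng.permutation(n)
    chosen: list[int] = []
    for cls in ("cancer", "normal"):
        cls_pool = [i for i in order if group[i] == cls]
        chosen.extend(cls_pool[:max(2, int(round(
            n_complete * (group == cls).sum() / n)))])
    complete_idx[np.array(chosen[:max(n_complete, 4)])] = True
    # each incomplete sample misses exactly one omic, keeping per-omic
    # coverage near the emulated cohort's (~72% of samples per platform)
    has_omic = {om: np.ones(n, dtype=bool) for om in OMICS}
    for i in np.nonzero(~complete_idx)[0]:
        has_omic[OMICS[rng.integers(0, 3)]][i] = False

    meta = pd.DataFrame({"group": group, "complete": complete_idx},
                        index=pd.Index(samples, name="sample_id"))
    for om in OMICS:
        meta[f"has_{om}"] = has_omic[om]

    truth = GroundTruth(informative={}, deg_direction={}, dms_label={},
                        regulator_map={})
    matrices: dict[str, OmicsMatrix] = {}
    is_cancer = group == "cancer"

    # --- expression omics -------------------------------------------------
    for om, p in (("mrna", spec.p_mrna), ("mirna", spec.p_mirna)):
        ids = _feature_ids("g" if om == "mrna" else "mir", p)
        base = rng.uniform(1.0, 6.0, size=p)       # log-scale baselines
        logx = base[None, :] + spec.noise_sd * rng.standard_normal((n, p))
        inf_ids = ids[:spec.k_informative]
        delta = spec.effect_size * spec.noise_sd
        for j, fid in enumerate(inf_ids):
            direction = "down" if j % 2 == 0 else "up"   # in cancer
            shift = -delta if direction == "down" else delta
            logx[is_cancer, j] += shift
            if om == "mrna":
                truth.deg_direction[fid] = direction
        truth.informative[om] = list(inf_ids)
        values = np.exp(logx)
        matrices[om] = OmicsMatrix(
            pd.DataFrame(values, index=samples, columns=ids), kind=om)

    # --- methylation ------------------------------------------------------
    p = spec.p_meth
    ids = _feature_ids("cg", p)
    shift = spec.resolved_beta_shift()
    mu = rng.uniform(0.15, 0.85, size=p)
    mu_c = mu.copy()
    inf_ids = ids[:spec.k_informative]
    for j, fid in enumerate(inf_ids):
        hyper = j % 2 == 0   # hyper-methylated in cancer: cancer beta higher
        lo, hi = 0.05 + shift, 0.95 - shift
        mu[j] = float(np.clip(mu[j], lo, hi))
        mu_c[j] = mu[j] + shift if hyper else mu[j] - shift
        truth.dms_label[fid] = "hyper" if hyper else "hypo"
        if shift == 0:
            truth.dms_label[fid] = "medium"
    kappa = spec.concentration
    site_mu = np.where(is_cancer[:, None], mu_c[None, :], mu[None, :])
    beta = rng.beta(site_mu * kappa, (1 - site_mu) * kappa)
    beta = np.clip(beta, 1e-6, 1 - 1e-6)
    truth.informative["meth"] = list(inf_ids)
    matrices["meth"] = OmicsMatrix(
        pd.DataFrame(beta, index=samples, columns=ids), kind="meth")

    # --- planted regulator map (mass regression experiments) --------------
    n_targets = min(spec.n_regulated_targets,
                    spec.p_mrna - spec.k_informative)
    if n_targets > 0 and spec.regulators_per_target > 0:
        mrna_ids = matrices["mrna"].features
        mir_ids = matrices["mirna"].features
        target_pool = mrna_ids[spec.k_informative:
                               spec.k_informative + n_targets]
        mir_log = np.log(matrices["mirna"].data.to_numpy())
        r = spec.regulation_r
        for t_id in target_pool:
            drivers = rng.choice(len(mir_ids),
                                 size=spec.regulators_per_target,
                                 replace=False)
            coefs = rng.uniform(0.8, 1.2, size=len(drivers)) * rng.choice(
                [-1.0, 1.0], size=len(drivers))
            signal = mir_log[:, drivers] @ coefs
            s_sd = signal.std()
            if s_sd == 0:
                continue
            noise_sd = s_sd * np.sqrt(1.0 / r ** 2 - 1.0)
            y = signal + noise_sd * rng.standard_normal(n)
            matrices["mrna"].data[t_id] = np.exp(
                (y - y.mean()) / y.std() + 3.0)
            truth.regulator_map[t_id] = [
                (mir_ids[d], float(c)) for d, c in zip(drivers, coefs)]

    # --- guard: no zero-variance features ---------------------------------
    for om in OMICS:
        df = matrices[om].data
        var = df.to_numpy().var(axis=0)
        for j in np.nonzero(var == 0)[0]:   # vanishingly unlikely; regenerate
            df.iloc[:, j] += rng.normal(0, 1e-6, size=n)

    # drop unavailable samples per omic
    for om in OMICS:
        keep = meta[f"has_{om}"].to_numpy()
        matrices[om] = OmicsMatrix(matrices[om].data.loc[keep],
                                   kind=om)
    return matrices, meta, truth


# ---------------------------------------------------------------------------
# Toy genome fixture
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenomeFixture:
    """A toy genome: sequences plus gene/CpGI/chromatin-state tracks and the
    coordinates assigned to every methylation feature."""

    sequences: dict[str, np.ndarray]     # uint8 base codes per chromosome
    genes: GenomicIntervalSet
    cpg_islands: GenomicIntervalSet
    chromatin_states: GenomicIntervalSet
    site_coords: pd.DataFrame            # index: site ID; chrom, pos

    _BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

    def sequence_str(self, chrom: str) -> str:
        return self.sequences[chrom].tobytes().decode()

    def fasta(self) -> dict[str, str]:
        return {c: self.sequence_str(c) for c in self.sequences}

    def gene_table(self) -> pd.DataFrame:
        """Genes with TSS (strand-aware) indexed by gene name."""
        df = self.genes.df.set_index("name").copy()
        df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
        return df


class PlacementError(RuntimeError):
    """Requested intervals could not be placed without overlap."""


def _place_intervals(n: int, lengths: np.ndarray, chrom_len: int,
                     rng: np.random.Generator,
                     max_tries: int = 2000) -> np.ndarray:
    """Place n non-overlapping intervals of the given lengths; returns starts."""
    placed: list[tuple[int, int]] = []
    starts = np.empty(n, dtype=int)
    for i in range(n):
        L = int(lengths[i])
        if L >= chrom_len:
            raise PlacementError("interval longer than chromosome")
        for _ in range(max_tries):
            s = int(rng.integers(0, chrom_len - L))
            if all(s + L <= a or s >= b for a, b in placed):
                placed.append((s, s + L))
                starts[i] = s
                break
        else:
            raise PlacementError(
                f"could not place interval {i} after {max_tries} tries")
    return starts


def generate_genome_fixture(n_chrom: int = 2, genes: int = 30, cpgi: int = 40,
                            seed: int = 0, chrom_length: int = 3_000_000,
                            meth_ids: Sequence[str] | None = None,
                            ) -> GenomeFixture:
    """Build a toy genome with gene, CpG-island and chromatin-state tracks.

    The chromatin-state track tiles each chromosome exactly once with the
    eight named states; genes and islands are non-overlapping within their
    track.  If ``meth_ids`` is given, each methylation feature is assigned a
    unique (chrom, position) coordinate.
    """
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    sequences = {
        c: GenomeFixture._BASE[rng.integers(0, 4, size=chrom_length)].copy()
        for c in chroms}

    gene_rows, cpgi_rows, state_rows = [], [], []
    per_chrom_genes = np.array_split(np.arange(genes), n_chrom)
    per_chrom_cpgi = np.array_split(np.arange(cpgi), n_chrom)
    for ci, chrom in enumerate(chroms):
        ng = len(per_chrom_genes[ci])
        # gene length range adapts so the requested count fits the chromosome
        hi = int(min(20000, max(2001, chrom_length // (2 * max(ng, 1)))))
        lengths = rng.integers(2000, hi, size=ng) if hi > 2000 \
            else np.full(ng, 2000)
        starts = _place_intervals(ng, lengths, chrom_length, rng)
        strands = rng.choice(["+", "-"], size=ng)
        for k, gi in enumerate(per_chrom_genes[ci]):
            gene_rows.append((chrom, int(starts[k]),
                              int(starts[k] + lengths[k]),
                              f"gene{gi:03d}", 0, strands[k]))
        nc = len(per_chrom_cpgi[ci])
        lengths = rng.integers(300, 2000, size=nc)
        starts = _place_intervals(nc, lengths, chrom_length, rng)
        for k, ii in enumerate(per_chrom_cpgi[ci]):
            cpgi_rows.append((chrom, int(starts[k]),
                              int(starts[k] + lengths[k]),
                              f"cpgi{ii:03d}", 0, "."))
        # chromatin-state tiling: random breakpoints, states cycle randomly
        n_seg = max(len(CHROMATIN_STATES), chrom_length // 100_000)
        cuts = np.sort(rng.choice(np.arange(1, chrom_length), size=n_seg - 1,
                                  replace=False))
        bounds = np.concatenate([[0], cuts, [chrom_length]])
        states = rng.permutation(
            np.resize(np.array(CHROMATIN_STATES), n_seg))
        for k in range(n_seg):
            state_rows.append((chrom, int(bounds[k]), int(bounds[k + 1]),
                               states[k], 0, "."))

    cols = GenomicIntervalSet.COLUMNS
    fixture = GenomeFixture(
        sequences=sequences,
        genes=GenomicIntervalSet(pd.DataFrame(gene_rows, columns=cols)),
        cpg_islands=GenomicIntervalSet(pd.DataFrame(cpgi_rows, columns=cols)),
        chromatin_states=GenomicIntervalSet(
            pd.DataFrame(state_rows, columns=cols)),
        site_coords=pd.DataFrame(columns=["chrom", "pos"]))
    if meth_ids is not None:
        fixture.site_coords = assign_site_coords(list(meth_ids), fixture, rng)
    return fixture


def assign_site_coords(meth_ids: Sequence[str], fixture: GenomeFixture,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Assign each methylation feature one unique genomic coordinate."""
    chroms = list(fixture.sequences)
    lengths = {c: len(fixture.sequences[c]) for c in chroms}
    n = len(meth_ids)
    chosen_chrom = rng.choice(chroms, size=n)
    rows = []
    used: set[tuple[str, int]] = set()
    for sid, chrom in zip(meth_ids, chosen_chrom):
        while True:
            pos = int(rng.integers(50, lengths[chrom] - 50))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        rows.append((sid, chrom, pos))
    return pd.DataFrame(rows, columns=["site", "chrom", "pos"]
                        ).set_index("site")


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def plant_motifs(fixture: GenomeFixture, pwms: Sequence[PWM],
                 dms_ids: Sequence[str], seed: int = 0,
                 flank: int = 20) -> list[dict]:
    """Write a sampled high-scoring site of a chosen PWM into the sequence
    around each given methylation site, so the site position falls inside the
    inserted motif instance and the instance stays fully inside the
    site +/- ``flank`` window (placement clamped at window edges).

    Mutates the fixture sequences in place and returns the insertion log.
    """
    rng = np.random.default_rng(seed)
    log_rows: list[dict] = []
    for k, sid in enumerate(dms_ids):
        if sid not in fixture.site_coords.index:
            raise KeyError(f"unknown methylation site {sid!r}")
        pwm = pwms[k % len(pwms)]
        w = pwm.width
        chrom = fixture.site_coords.loc[sid, "chrom"]
        pos = int(fixture.site_coords.loc[sid, "pos"])
        seq = fixture.sequences[chrom]
        win_lo = max(0, pos - flank)
        win_hi = min(len(seq), pos + flank + 1)
        lo = max(win_lo, pos - w + 1)
        hi = min(win_hi - w, pos)
        if hi < lo:       # motif wider than the window; clamp to window start
            lo = hi = max(win_lo, min(pos, win_hi - w))
        start = int(rng.integers(lo, hi + 1))
        site = pwm.sample_site(rng)
        seq[start:start + w] = np.frombuffer(site.encode(), dtype=np.uint8)
        log_rows.append({"site": sid, "chrom": chrom, "pos": pos,
                         "motif": pwm.name, "start": start, "end": start + w,
                         "inserted": site})
    return log_rows


def demo_pwms(n: int = 3, width: int = 10, seed: int = 0,
              sharpness: float = 0.9) -> list[PWM]:
    """Information-rich random PWMs for planting and scanning tests."""
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n):
        probs = np.full((width, 4), (1 - sharpness) / 3)
        top = rng.integers(0, 4, size=width)
        probs[np.arange(width), top] = sharpness
        pwms.append(PWM(name=f"TF{i:02d}", probs=probs))
    return pwms


# ---------------------------------------------------------------------------
# Gene-description corpus
# ---------------------------------------------------------------------------

_SYLLABLES = ["ka", "lo", "mi", "ru", "ta", "ve", "zo", "ne", "pi", "su",
              "ga", "de", "fo", "hy", "ju"]


def _make_words(n: int, tag: str, rng: np.random.Generator) -> list[str]:
    words = set()
    while len(words) < n:
        w = tag + "".join(rng.choice(_SYLLABLES, size=3))
        words.add(w)
    return sorted(words)


def generate_descriptions(genes: Sequence[str], k_topics: int = 3,
                          topic_vocab: int = 30, shared_vocab: int = 40,
                          words_per_doc: int = 60, topic_weight: float = 0.6,
                          seed: int = 0
                          ) -> tuple[dict[str, str], dict[str, int]]:
    """Generate one text document per gene with planted topic clusters.

    Each document mixes shared vocabulary with its topic's own disjoint
    vocabulary (``topic_weight`` fraction of tokens).  Returns the corpus and
    the planted topic assignment.
    """
    if not genes:
        raise ParameterError("at least one gene is required")
    if words_per_doc < 1:
        raise ParameterError("empty descriptions requested")
    rng = np.random.default_rng(seed)
    shared = _make_words(shared_vocab, "com", rng)
    topics = [_make_words(topic_vocab, f"top{t}", rng)
              for t in range(k_topics)]
    corpus: dict[str, str] = {}
    assignment: dict[str, int] = {}
    for i, gene in enumerate(genes):
        t = i % k_topics
        assignment[gene] = t
        n_topic = int(round(topic_weight * words_per_doc)) if k_topics > 1 \
            else 0
        n_shared = words_per_doc - n_topic
        toks = list(rng.choice(topics[t], size=n_topic)) + \
            list(rng.choice(shared, size=n_shared))
        rng.shuffle(toks)
        corpus[gene] = " ".join(toks)
    return corpus, assignment


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def generate_survival(meta: pd.DataFrame, beta: pd.DataFrame,
                      effect_dms_ids: Sequence[str], hazard_ratio: float = 3.0,
                      baseline_rate: float = 0.1, censor_rate: float = 0.05,
                      seed: int = 0) -> pd.DataFrame:
    """Add exponential survival columns to the sample metadata.

    A sample's hazard is the baseline multiplied by ``hazard_ratio`` for every
    effect site at which its beta-value exceeds that site's median.  Censoring
    is independent exponential; every time is strictly positive.
    """
    rng = np.random.default_rng(seed)
    samples = [s for s in meta.index if s in beta.index]
    hazard = np.full(len(samples), baseline_rate, dtype=float)
    for sid in effect_dms_ids:
        vals = beta.loc[samples, sid]
        high = (vals > vals.median()).to_numpy()
        hazard[high] *= hazard_ratio
    event_t = rng.exponential(1.0 / hazard)
    censor_t = rng.exponential(1.0 / censor_rate, size=len(samples))
    time = np.minimum(event_t, censor_t)
    time = np.maximum(time, 1e-9)
    out = meta.copy()
    out.loc[samples, "time"] = time
    out.loc[samples, "event"] = (event_t <= censor_t).astype(int)
    return out


# ---------------------------------------------------------------------------
# Cis-regulatory pair planting
# ---------------------------------------------------------------------------

def plant_cis_pair(mrna: OmicsMatrix, meth: OmicsMatrix, gene: str, site: str,
                   negative: bool = True, noise_sd: float = 0.05,
                   seed: int = 0) -> None:
    """Overwrite a methylation column with a monotone (logistic) transform of
    a gene's expression plus small noise, planting a cis-correlated pair."""
    rng = np.random.default_rng(seed)
    common = mrna.data.index.intersection(meth.data.index)
    x = np.log(mrna.data.loc[common, gene].to_numpy())
    z = (x - x.mean()) / (x.std() + 1e-12)
    if negative:
        z = -z
    b = 1.0 / (1.0 + np.exp(-1.5 * z)) + noise_sd * rng.standard_normal(len(z))
    meth.data.loc[common, site] = np.clip(b, 1e-6, 1 - 1e-6)
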