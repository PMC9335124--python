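"""Enrichment analysis of phage-display deep-sequencing counts.

Per-sample peptide lists become a peptide x sample count matrix; counts are
normalized to parts-per-million (ppm) of each sample's accepted reads; a
peptide is called target-enriched when, against EVERY control selection arm
(naive library R0, round-1 pool R1, bead-only and unrelated-antibody round-2
controls), its mean target abundance is at least ``min_ratio`` times the
control mean and a one-tailed unequal-variance (Welch) t-test across
replicates gives p <= alpha.  No multiple-testing correction is applied and
abundances are tested on the raw ppm scale.

Hit sequences can be clustered by embedding each residue as its BLOSUM62
substitution-score row and applying average-linkage agglomerative
clustering on Euclidean distance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from Bio.Align import substitution_matrices

from pepbinder.io import AMINO_ACIDS

CONDITIONS = ("R0", "R1", "R2_target", "R2_beads", "R2_unrelated", "other")
DEFAULT_CONTROLS = ("R0", "R1", "R2_beads", "R2_unrelated")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    condition: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


@dataclass
class CountMatrix:
    """Peptide x sample read counts with sample metadata."""

    peptides: list[str]
    samples: list[SampleMeta]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.peptides), len(self.samples)):
            raise ValueError("counts shape does not match peptides x samples")
        if len(set(self.peptides)) != len(self.peptides):
            raise ValueError("duplicate peptide rows")
        seen = set()
        for s in self.samples:
            key = (s.condition, s.replicate)
            if key in seen:
                raise ValueError(f"duplicate (condition, replicate) {key}")
            seen.add(key)
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def columns_for(self, condition: str) -> list[int]:
        cols = [j for j, s in enumerate(self.samples) if s.condition == condition]
        if not cols:
            raise ValueError(f"condition {condition!r} absent from matrix")
        return cols


@dataclass(frozen=True)
class EnrichmentResult:
    peptide: str
    ratio_per_control: dict = field(hash=False)
    p_per_control: dict = field(hash=False)
    is_hit: bool = False


def build_count_matrix(per_sample_peptides: dict, meta: list[SampleMeta]) -> CountMatrix:
    """Tabulate per-sample peptide multiplicities into a CountMatrix.

    Rows are the union of observed peptides in first-observation order;
    empty samples yield zero columns.
    """
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in metadata")
    unknown = set(per_sample_peptides) - set(ids)
    if unknown:
        raise ValueError(f"sample_id(s) not in metadata: {sorted(unknown)}")
    peptides: list[str] = []
    index: dict[str, int] = {}
    counters = {}
    for sid in ids:
        c = Counter(per_sample_peptides.get(sid, []))
        counters[sid] = c
        for pep in per_sample_peptides.get(sid, []):
            if pep not in index:
                index[pep] = len(peptides)
                peptides.append(pep)
    counts = np.zeros((len(peptides), len(ids)), dtype=np.int64)
    for j, sid in enumerate(ids):
        for pep, n in counters[sid].items():
            counts[index[pep], j] = n
    return CountMatrix(peptides=peptides, samples=list(meta), counts=counts)


def normalize_ppm(cm: CountMatrix) -> np.ndarray:
    """Counts as parts-per-million of each sample's total accepted reads."""
    totals = cm.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [cm.samples[j].sample_id for j in zero]
        raise ValueError(f"zero total count for sample(s) {names}")
    return cm.counts / totals * 1e6


def welch_t_one_tailed(a, b) -> tuple[float, float]:
    """One-tailed Welch t-test of mean(a) > mean(b).

    Returns (t, p) with the Welch–Satterthwaite degrees of freedom and
    p = P(T_df > t).  Degenerate zero-variance inputs are resolved by the
    limit: equal means give (0, 0.5), unequal means give (+/-inf, 0 or 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_one_tailed requires >= 2 replicates per group")
    t, p = _welch_rows(a[None, :], b[None, :])
    return float(t[0]), float(p[0])


def _welch_rows(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch statistic and upper-tail p over matrices of replicates."""
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = ma - mb
    t = np.zeros_like(diff)
    p = np.full_like(diff, 0.5)
    ok = se2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t[ok] = diff[ok] / np.sqrt(se2[ok])
        df = se2[ok] ** 2 / (
            (va[ok] / na) ** 2 / (na - 1) + (vb[ok] / nb) ** 2 / (nb - 1)
        )
    p[ok] = stats.t.sf(t[ok], df)
    # zero pooled variance: all replicates identical within each group
    deg = ~ok
    t[deg & (diff > 0)] = np.inf
    p[deg & (diff > 0)] = 0.0
    t[deg & (diff < 0)] = -np.inf
    p[deg & (diff < 0)] = 1.0
    return t, p


def call_enriched(
    cm: CountMatrix,
    target: str = "R2_target",
    controls: tuple[str, ...] = DEFAULT_CONTROLS,
    min_ratio: float = 2.0,
    alpha: float = 0.05,
    pseudo_ppm: float = 1.0,
    control_mode: str = "each",
) -> list[EnrichmentResult]:
    """Call target-enriched peptides against every listed control arm.

    Per peptide and control group, ratio = mean target ppm /
    max(mean control ppm, ``pseudo_ppm``); p from the one-tailed Welch test
    on the ppm replicate vectors.  ``is_hit`` requires ratio >= ``min_ratio``
    and p <= ``alpha`` against ALL control groups.  ``control_mode='pooled'``
    concatenates all control replicates into one comparison group.
    """
    ppm = normalize_ppm(cm)
    tcols = cm.columns_for(target)
    if len(tcols) < 2:
        raise ValueError("target condition needs >= 2 replicates")
    T = ppm[:, tcols]
    tmean = T.mean(axis=1)

    if control_mode == "pooled":
        cols = [j for c in controls for j in cm.columns_for(c)]
        groups = {"pooled": cols}
    elif control_mode == "each":
        groups = {c: cm.columns_for(c) for c in controls}
    else:
        raise ValueError("control_mode must be 'each' or 'pooled'")

    ratios, pvals = {}, {}
    for name, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"control group {name!r} needs >= 2 replicates")
        C = ppm[:, cols]
        ratios[name] = tmean / np.maximum(C.mean(axis=1), pseudo_ppm)
        _, pvals[name] = _welch_rows(T, C)

    results = []
    for i, pep in enumerate(cm.peptides):
        r = {g: float(ratios[g][i]) for g in groups}
        p = {g: float(pvals[g][i]) for g in groups}
        hit = all(r[g] >= min_ratio and p[g] <= alpha for g in groups)
        results.append(EnrichmentResult(peptide=pep, ratio_per_control=r, p_per_control=p, is_hit=hit))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"peptide": r.peptide, "is_hit": r.is_hit}
        for g, v in r.ratio_per_control.items():
            row[f"ratio_{g}"] = v
        for g, v in r.p_per_control.items():
            row[f"p_{g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def blosum62_embed(peptides: list[str]) -> np.ndarray:
    """Embed equal-length peptides as concatenated BLOSUM62 rows (20L dims)."""
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise ValueError(f"peptides must share one length, got lengths {sorted(lengths)}")
    mat = substitution_matrices.load("BLOSUM62")
    rows = {a: np.array([mat[a, b] for b in AMINO_ACIDS], dtype=float) for a in AMINO_ACIDS}
    return np.vstack([np.concatenate([rows[ch] for ch in p]) for p in peptides])


def cluster_hits(hits: list[str], n_clusters: int = 5) -> dict[str, int]:
    """Group hit peptides by BLOSUM62-profile similarity.

    Average-linkage agglomerative clustering on Euclidean distance between
    BLOSUM62 row-concatenation embeddings, cut at ``n_clusters``; every
    peptide receives a cluster id.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    uniq = list(dict.fromkeys(hits))
    if n_clusters > len(uniq):
        raise ValueError(f"n_clusters={n_clusters} exceeds {len(uniq)} distinct peptides")
    X = blosum62_embed(uniq)
    if len(uniq) == 1 or n_clusters == 1:
        return {p: 0 for p in hits}
    model = AgglomerativeClustering(n_clusters=n_clusters, linkage="average", metric="euclidean")
    labels = model.fit_predict(X)
    assign = dict(zip(uniq, (int(v) for v in labels)))
    return {p: assign[p] for p in hits}
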