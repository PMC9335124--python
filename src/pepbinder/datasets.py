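"""Machine-learning dataset preparation.

Enriched peptides become training data via three steps: redundancy removal
(greedy incremental clustering at a sequence-identity threshold, CD-HIT
style), screening against a local table of target-unrelated peptides (TUPs
— sequences recurrently selected by four or more entirely different
targets), and balanced pairing of the positives with disjoint equal-size
negative samples into n sub-datasets (one SVM submodel is trained per
sub-dataset).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from pepbinder.io import Peptide


@dataclass(frozen=True)
class TUPRecord:
    """A peptide with the set of unrelated targets it has been selected by."""

    seq: str
    targets: frozenset

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("TUPRecord needs at least one target")


@dataclass
class SubDataset:
    """One balanced positive/negative pairing."""

    positives: list[Peptide]
    negatives: list[Peptide]

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("sub-dataset must be balanced")
        overlap = {p.seq for p in self.positives} & {n.seq for n in self.negatives}
        if overlap:
            raise ValueError(f"sequences in both classes: {sorted(overlap)[:3]}")


def _match_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner


_ALIGNER = _match_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Sequence identity in [0, 1], CD-HIT convention.

    Equal lengths: ungapped matching positions / length.  Unequal lengths:
    global-alignment matches divided by the shorter sequence's length.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(a) == len(b):
        return sum(x == y for x, y in zip(a, b)) / len(a)
    matches = _ALIGNER.score(a, b)
    return matches / min(len(a), len(b))


def remove_redundancy(peptides: list[Peptide], threshold: float = 0.8) -> list[Peptide]:
    """Greedy incremental redundancy removal at an identity threshold.

    Candidates are visited longest-first (lexicographic tie-break); a
    peptide with identity >= ``threshold`` to any existing representative is
    absorbed, otherwise it founds a new cluster.  Representatives are
    returned in their original input order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(peptides, key=lambda p: (-len(p.seq), p.seq))
    reps: list[Peptide] = []
    for cand in order:
        if not any(pairwise_identity(cand.seq, r.seq) >= threshold for r in reps):
            reps.append(cand)
    kept = {id(p) for p in reps}
    return [p for p in peptides if id(p) in kept]


def read_tup_table(path) -> list[TUPRecord]:
    """Read a TSV with columns (seq, target), one row per peptide-target
    pair, aggregated into TUPRecords."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"seq", "target"} <= set(df.columns):
        raise ValueError(f"{path}: TUP table needs columns (seq, target)")
    agg: dict[str, set] = defaultdict(set)
    for r in df.itertuples():
        agg[r.seq.upper()].add(r.target)
    return [TUPRecord(seq=s, targets=frozenset(t)) for s, t in agg.items()]


def screen_tups(
    peptides: list[Peptide], tup_table: list[TUPRecord], min_targets: int = 4
) -> dict[str, str]:
    """Flag putative target-unrelated peptides by exact-sequence lookup.

    A peptide recorded with ``min_targets`` or more entirely different
    targets is flagged ``putative_TUP(n)``; everything else is ``clean``.
    """
    lookup = {t.seq: len(t.targets) for t in tup_table}
    out = {}
    for p in peptides:
        n = lookup.get(p.seq, 0)
        out[p.seq] = f"putative_TUP({n})" if n >= min_targets else "clean"
    return out


def build_sub_datasets(
    positives: list[Peptide],
    negatives: list[Peptide],
    n_pairs: int = 10,
    seed: int = 1,
) -> list[SubDataset]:
    """Balanced sub-dataset construction.

    Samples ``n_pairs * len(positives)`` negatives without replacement
    (seeded), partitions them into ``n_pairs`` disjoint groups, and pairs
    each group with the full positive set.  Deterministic given the seed.
    """
    n_pos = len(positives)
    need = n_pairs * n_pos
    if len(negatives) < need:
        raise ValueError(
            f"need at least {need} negatives for {n_pairs} balanced sub-datasets "
            f"of {n_pos}, got {len(negatives)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(negatives), size=need, replace=False)
    subs = []
    for k in range(n_pairs):
        group = [negatives[i] for i in chosen[k * n_pos : (k + 1) * n_pos]]
        subs.append(SubDataset(positives=list(positives), negatives=group))
    return subs
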