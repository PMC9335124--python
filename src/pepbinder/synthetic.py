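"""Seeded synthetic data: benchmark peptide sets and phage-display counts.

Two generators stand in for wet-lab selections so every pipeline stage can
be exercised end-to-end:

* **Benchmark peptides** — positives carry a position-weight-matrix motif
  mixed into a uniform residue background with strength ``separation``
  in [0, 1] (0 = indistinguishable from background, 1 = full motif);
  negatives are i.i.d. background.  The canonical shape is 80 positives
  vs 800 negatives split into 10 balanced sub-datasets.
* **Phage-display counts** — library abundances drawn from a symmetric
  Dirichlet; each target-selection round multiplies the planted binders'
  weights by ``enrichment_factor`` in target arms only, round-2 control
  arms reselect the round-1 pool with replicate noise only; per-sample
  read counts are multinomial at the configured depth.  Planted binders
  thus show a true target/control abundance ratio near the enrichment
  factor — high in the round-2 target arm and low in the naive library,
  round-1 pool, bead-only, and unrelated-antibody controls — never a
  ratio written into the counts directly.

What this emulates and what it does not: replicate overdispersion is
modeled by per-replicate lognormal weight jitter on top of multinomial
sampling; amplification bias, sequencing error, and collapsed parasite
(fast-growing phage) dynamics are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pepbinder.enrichment import CountMatrix, SampleMeta
from pepbinder.io import AMINO_ACIDS, Peptide


@dataclass(frozen=True)
class MotifModel:
    """Per-position residue probabilities plus a background-mixing strength."""

    weights: tuple  # length L of 20-vectors over AMINO_ACIDS order
    implant_strength: float = 1.0

    def __post_init__(self) -> None:
        for w in self.weights:
            if len(w) != 20 or abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("each position's probabilities must be a 20-vector summing to 1")
        if not 0 <= self.implant_strength <= 1:
            raise ValueError("implant_strength must be in [0, 1]")

    @property
    def length(self) -> int:
        return len(self.weights)


def default_motif(length: int = 12, strength: float = 1.0) -> MotifModel:
    """A 12-mer binding motif with six fixed anchor residues
    (aromatic/proline/charged anchors typical of display-selected binders)
    interleaved with unconstrained positions.  At implant strength s each
    position follows s * motif + (1 - s) * background, so s tunes
    separability continuously from background (0) to the full motif (1)."""
    anchors = {0: "W", 2: "H", 4: "Y", 6: "P", 8: "D", 10: "F"}
    uniform = np.full(20, 0.05)
    weights = []
    for i in range(length):
        if i in anchors:
            w = np.zeros(20)
            w[AMINO_ACIDS.index(anchors[i])] = 1.0
        else:
            w = uniform.copy()
        weights.append(tuple(w))
    return MotifModel(weights=tuple(weights), implant_strength=strength)


@dataclass(frozen=True)
class NGPDSimConfig:
    """Study-shaped selection layout: naive library and round-1 pool in
    triplicate, round-2 target arm in six replicates, bead-only and
    unrelated-antibody round-2 controls in triplicate."""

    library_size: int = 5000
    depth: int = 100_000
    replicates: dict = field(
        default_factory=lambda: {
            "R0": 3, "R1": 3, "R2_target": 6, "R2_beads": 3, "R2_unrelated": 3,
        }
    )
    enrichment_factor: float = 10.0
    dirichlet_concentration: float = 1.0
    replicate_noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.library_size < 1 or self.depth < 1:
            raise ValueError("library_size and depth must be positive")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if any(r < 1 for r in self.replicates.values()):
            raise ValueError("replicate counts must be positive")


def gen_background_peptides(
    n: int, length: int = 12, aa_freqs=None, seed: int = 0
) -> list[Peptide]:
    """n i.i.d. random peptides from the residue frequency vector (uniform
    over the 20 standard amino acids by default)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if aa_freqs is None:
        aa_freqs = np.full(20, 0.05)
    aa_freqs = np.asarray(aa_freqs, dtype=float)
    if aa_freqs.shape != (20,) or abs(aa_freqs.sum() - 1.0) > 1e-9:
        raise ValueError("aa_freqs must be 20 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    draws = rng.choice(20, size=(n, length), p=aa_freqs)
    return [
        Peptide(id=f"bg{i}", seq="".join(letters[row]), label="negative")
        for i, row in enumerate(draws)
    ]


def gen_motif_positives(n: int, motif: MotifModel, seed: int = 0, length: int | None = None) -> list[Peptide]:
    """n peptides with each position drawn from
    implant_strength * motif + (1 - implant_strength) * uniform background."""
    if length is not None and length != motif.length:
        raise ValueError("motif length must equal peptide length")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    s = motif.implant_strength
    uniform = np.full(20, 0.05)
    cols = []
    for w in motif.weights:
        p = s * np.asarray(w) + (1 - s) * uniform
        cols.append(rng.choice(20, size=n, p=p / p.sum()))
    mat = np.column_stack(cols)
    return [
        Peptide(id=f"pos{i}", seq="".join(letters[row]), label="positive")
        for i, row in enumerate(mat)
    ]


def gen_ngpd_counts(
    cfg: NGPDSimConfig, planted: set[str] | None = None, library: list[str] | None = None
) -> tuple[CountMatrix, dict[str, bool]]:
    """Simulate selection-round count data with planted true binders.

    Returns the CountMatrix and a per-peptide truth map (True = planted).
    Deterministic given ``cfg`` (including its seed).
    """
    rng = np.random.default_rng(cfg.seed)
    if library is None:
        library = [p.seq for p in gen_background_peptides(cfg.library_size, seed=cfg.seed)]
        # random 12-mers at this scale are almost surely unique; guard anyway
        library = list(dict.fromkeys(library))
    if planted is None:
        planted = set()
    missing = set(planted) - set(library)
    if missing:
        raise ValueError(f"planted peptide(s) not in library: {sorted(missing)[:3]}")
    n = len(library)
    planted_mask = np.array([p in planted for p in library])

    base = rng.dirichlet(np.full(n, cfg.dirichlet_concentration))
    f = cfg.enrichment_factor
    arm_weights = {}
    for cond, rounds_of_selection in (
        ("R0", 0), ("R1", 1), ("R2_target", 2), ("R2_beads", 1), ("R2_unrelated", 1),
    ):
        w = base * np.where(planted_mask, f**rounds_of_selection, 1.0)
        arm_weights[cond] = w / w.sum()

    samples, columns = [], []
    for cond, n_rep in cfg.replicates.items():
        for rep in range(1, n_rep + 1):
            noise = rng.lognormal(0.0, cfg.replicate_noise_sigma, size=n)
            w = arm_weights[cond] * noise
            w /= w.sum()
            columns.append(rng.multinomial(cfg.depth, w))
            samples.append(SampleMeta(sample_id=f"{cond}_rep{rep}", condition=cond, replicate=rep))
    cm = CountMatrix(peptides=list(library), samples=samples, counts=np.column_stack(columns))
    truth = {p: bool(m) for p, m in zip(library, planted_mask)}
    return cm, truth


def gen_benchmark(
    n_pos: int = 80,
    n_neg: int = 800,
    separation: float = 1.0,
    seed: int = 0,
    length: int = 12,
) -> list[Peptide]:
    """Labeled benchmark peptides: motif positives at the given separation
    strength plus background negatives, shuffled; seeded and deterministic."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    motif = default_motif(length=length, strength=separation)
    pos = gen_motif_positives(n_pos, motif, seed=seed)
    neg = gen_background_peptides(n_neg, length=length, seed=seed + 1)
    all_peps = pos + neg
    rng = np.random.default_rng(seed + 2)
    order = rng.permutation(len(all_peps))
    return [all_peps[i] for i in order]
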