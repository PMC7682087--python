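"""Synthetic peptide-window and protein generator with planted class signal.

Real malonylated and unmodified lysine peptides differ in flank
composition: glycine, leucine, alanine and valine are over-represented
around modified lysines, while lysine and glutamate are
over-represented around unmodified ones.  The generator plants exactly
that kind of positional-composition signal: each non-center position of
a window is drawn from a background composition re-weighted per class,

    weight(r | class) = background(r) * (1 + effect_size * boost_class(r)),

with the center position fixed to K.  ``effect_size = 0`` makes the two
classes exchangeable (a null generator for calibration tests);
the default ``effect_size = 1`` with boost 2.0 on the enriched residues
is a strong, easily detectable signal.  A fraction of windows simulate
sequence edges by replacing a random-length prefix or suffix with the
padding residue X.

An optional pair-coupling mode additionally plants a k-spaced residue
pair preference in positives, a signal invisible to per-position
marginals but visible to the k-spaced pair encoder.

``generate_protein_fixture`` embeds the same class-conditional flanks
into full-length proteins with annotated sites, exercising FASTA
parsing and window extraction end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .windows import AA20, PAD, PeptideWindow, ProteinRecord, SiteAnnotation

DEFAULT_POS_BOOST = {"G": 2.0, "L": 2.0, "A": 2.0, "V": 2.0}
DEFAULT_NEG_BOOST = {"K": 2.0, "E": 2.0}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the planted-signal window generator."""

    n_pos: int = 1000
    n_neg: int = 1000
    window_length: int = 17
    enriched_pos: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POS_BOOST)
    )
    enriched_neg: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NEG_BOOST)
    )
    effect_size: float = 1.0
    background: Mapping[str, float] | None = None  # None = uniform over AA20
    edge_padding_rate: float = 0.1
    pair_coupling: tuple[int, str, float] | None = None  # (k, two-residue pair, rate)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length < 3 or self.window_length % 2 == 0:
            raise ValueError("window_length must be odd and >= 3")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("window counts must be non-negative")
        if not 0.0 <= self.edge_padding_rate <= 1.0:
            raise ValueError("edge_padding_rate must be in [0, 1]")
        for m in (self.enriched_pos, self.enriched_neg):
            bad = set(m) - set(AA20)
            if bad:
                raise ValueError(f"boost map names non-standard residues: {sorted(bad)}")
        if self.pair_coupling is not None:
            k, pair, rate = self.pair_coupling
            if k < 0 or len(pair) != 2 or not 0 <= rate <= 1:
                raise ValueError("pair_coupling must be (k >= 0, 2-residue pair, rate in [0,1])")

    @property
    def flank(self) -> int:
        return (self.window_length - 1) // 2


def class_distribution(config: GeneratorConfig, label: int) -> np.ndarray:
    """Per-position residue distribution over AA20 for the given class."""
    if config.background is None:
        base = np.full(len(AA20), 1.0 / len(AA20))
    else:
        base = np.array([config.background.get(r, 0.0) for r in AA20], dtype=float)
        if base.sum() <= 0:
            raise ValueError("background composition must have positive mass")
        base = base / base.sum()
    boost = config.enriched_pos if label == 1 else config.enriched_neg
    weights = base * np.array(
        [1.0 + config.effect_size * boost.get(r, 0.0) for r in AA20]
    )
    if (weights < 0).any():
        raise ValueError("negative probability after boosting; reduce effect_size")
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate class distribution")
    return weights / total


#: Human-proteome-like background composition (UniProt/Swiss-Prot order
#: of magnitude), offered as an alternative to the uniform default.
PROTEOME_BACKGROUND = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.054, "V": 0.060, "W": 0.012, "Y": 0.027,
}


def _sample_window(
    rng: np.random.Generator, config: GeneratorConfig, dist: np.ndarray, label: int
) -> PeptideWindow:
    L, c = config.window_length, config.flank
    chars = list("".join(rng.choice(list(AA20), size=L, p=dist)))
    chars[c] = "K"
    if config.pair_coupling is not None and label == 1:
        k, pair, rate = config.pair_coupling
        if rng.random() < rate:
            starts = [i for i in range(L - k - 1) if i != c and i + k + 1 != c]
            if starts:
                i = int(rng.choice(starts))
                chars[i], chars[i + k + 1] = pair[0], pair[1]
    if rng.random() < config.edge_padding_rate:
        side = rng.integers(2)
        pad_len = int(rng.integers(1, c + 1))
        if side == 0:
            chars[:pad_len] = [PAD] * pad_len
        else:
            chars[L - pad_len:] = [PAD] * pad_len
    return PeptideWindow(
        residues="".join(chars), n=c, eps=c, label=label, source="synthetic"
    )


def generate_windows(config: GeneratorConfig) -> list[PeptideWindow]:
    """Generate ``n_pos`` positive then ``n_neg`` negative windows."""
    rng = np.random.default_rng(config.seed)
    pos_dist = class_distribution(config, 1)
    neg_dist = class_distribution(config, 0)
    out = [_sample_window(rng, config, pos_dist, 1) for _ in range(config.n_pos)]
    out += [_sample_window(rng, config, neg_dist, 0) for _ in range(config.n_neg)]
    return out


def generate_protein_fixture(
    n_proteins: int,
    length_range: tuple[int, int],
    site_density: float,
    config: GeneratorConfig | None = None,
) -> tuple[str, str, list[ProteinRecord], list[SiteAnnotation]]:
    """Synthetic proteins with annotated lysine sites.

    Annotated sites are spaced at least a window length apart so their
    class-conditional flanks never overlap; flank residues inside the
    protein follow the class distribution, and sites near the termini
    exercise X-padding on extraction.  ``site_density`` is the expected
    number of annotated sites per residue (sites per position, small).
    Returns (FASTA text, annotation TSV text, records, annotations).
    """
    if config is None:
        config = GeneratorConfig()
    if not 0.0 <= site_density <= 1.0 / config.window_length:
        raise ValueError(
            f"site_density must be in [0, {1.0 / config.window_length:.4f}]"
        )
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length_range")
    rng = np.random.default_rng(config.seed)
    pos_dist = class_distribution(config, 1)
    neg_dist = class_distribution(config, 0)
    bg = class_distribution(
        GeneratorConfig(effect_size=0.0, background=config.background), 1
    )
    flank = config.flank

    records: list[ProteinRecord] = []
    annotations: list[SiteAnnotation] = []
    fasta_lines: list[str] = []
    for p in range(n_proteins):
        L = int(rng.integers(lo, hi + 1))
        seq = list("".join(rng.choice(list(AA20), size=L, p=bg)))
        n_sites = rng.binomial(L, site_density)
        placed: list[int] = []
        for _ in range(n_sites):
            candidates = [
                i for i in range(L)
                if all(abs(i - j) >= config.window_length for j in placed)
            ]
            if not candidates:
                break
            i = int(rng.choice(candidates))
            placed.append(i)
            label = int(rng.integers(2))
            dist = pos_dist if label == 1 else neg_dist
            for off in range(-flank, flank + 1):
                j = i + off
                if 0 <= j < L:
                    seq[j] = "K" if off == 0 else str(rng.choice(list(AA20), p=dist))
            annotations.append(
                SiteAnnotation(protein_id=f"synth{p}", position=i + 1, label=label)
            )
        records.append(ProteinRecord(id=f"synth{p}", sequence="".join(seq)))
        fasta_lines.append(f">synth{p}")
        fasta_lines.append("".join(seq))
    fasta_text = "\n".join(fasta_lines) + "\n"
    tsv_lines = ["protein_id\tposition\tlabel"]
    tsv_lines += [f"{a.protein_id}\t{a.position}\t{a.label}" for a in annotations]
    return fasta_text, "\n".join(tsv_lines) + "\n", records, annotations
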