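"""Synthetic TM-like fragment benchmark with planted, position-recorded motifs.

Positives carry exactly one instantiated motif template (GxxxG-type, serine
zipper, or leucine heptad) at a uniformly sampled position; negatives are
hydrophobic-biased background sequences rejected-and-resampled until they
contain no exact match to any template pattern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataio import AMINO_ACIDS, DIMER, NON_DIMER, Fragment

WILDCARD = "x"


@dataclass(frozen=True)
class MotifTemplate:
    """A sequence pattern with fixed residues and wildcard positions.

    ``pattern`` uses amino-acid letters for fixed positions and ``x`` for
    wildcards, e.g. ``"GxxxG"``.
    """

    name: str
    pattern: str

    def __post_init__(self) -> None:
        for ch in self.pattern:
            if ch != WILDCARD and ch not in AMINO_ACIDS:
                raise ValueError(
                    f"template {self.name!r}: invalid pattern character {ch!r}"
                )
        if not self.pattern:
            raise ValueError(f"template {self.name!r}: empty pattern")

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def fixed_positions(self) -> dict[int, str]:
        return {i: ch for i, ch in enumerate(self.pattern) if ch != WILDCARD}

    @property
    def regex(self) -> re.Pattern:
        return re.compile(self.pattern.replace(WILDCARD, "."))

    def matches_at(self, sequence: str, position: int) -> bool:
        """True if every fixed position of the pattern matches *sequence* at *position*."""
        if position + self.length > len(sequence):
            return False
        return all(
            sequence[position + i] == ch for i, ch in self.fixed_positions.items()
        )


#: The three classic dimerization interface families: a glycophorin-A-style
#: GxxxG interface (GVxxGVxxT), a serine-zipper polar interface (SxxSSxxT),
#: and a leucine heptad repeat with hydrophobic first positions (IxxL...).
DEFAULT_TEMPLATES: tuple[MotifTemplate, ...] = (
    MotifTemplate("gxxxg", "GVxxGVxxT"),
    MotifTemplate("polar_zipper", "SxxSSxxT"),
    MotifTemplate("leucine_heptad", "IxxLxxxIxxLxxxIxxL"),
)

#: Hydrophobic-enriched residue frequencies (L+I+V+F+A+G carry 66% of the
#: mass), mimicking transmembrane helix composition; small/polar motif anchor
#: residues (G, S, T) are kept rare, as they are in TM helices.
DEFAULT_BACKGROUND: dict[str, float] = {
    "L": 0.20, "I": 0.05, "V": 0.14, "A": 0.13, "F": 0.11, "G": 0.03,
    "M": 0.05, "T": 0.04, "S": 0.03, "Y": 0.04, "W": 0.03,
    "C": 0.02, "P": 0.02, "N": 0.02, "Q": 0.02, "H": 0.02, "K": 0.02,
    "R": 0.01, "D": 0.01, "E": 0.01,
}

_MAX_REJECTIONS = 10_000


@dataclass
class SimulationConfig:
    """Parameters of the synthetic benchmark.

    ``n_positive``/``n_negative`` default to the 524 : 1,413 class ratio of the
    benchmark this generator emulates.
    """

    n_positive: int = 524
    n_negative: int = 1413
    fragment_length: int = 40
    motif_templates: Sequence[MotifTemplate] = DEFAULT_TEMPLATES
    background_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("class counts must be non-negative")
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be positive")
        total = sum(self.background_distribution.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"background_distribution sums to {total:.6f}, expected 1.0"
            )
        for aa in self.background_distribution:
            if aa not in AMINO_ACIDS:
                raise ValueError(f"background_distribution: invalid residue {aa!r}")
        if self.motif_templates:
            longest = max(t.length for t in self.motif_templates)
            if self.fragment_length < longest:
                raise ValueError(
                    f"fragment_length {self.fragment_length} is shorter than the "
                    f"longest motif template ({longest})"
                )

    @property
    def _letters_probs(self) -> tuple[np.ndarray, np.ndarray]:
        letters = np.array(sorted(self.background_distribution))
        probs = np.array([self.background_distribution[a] for a in letters])
        return letters, probs / probs.sum()


def sample_background(
    length: int, config: SimulationConfig, rng: np.random.Generator
) -> Fragment:
    """Draw a non-dimer fragment of *length* i.i.d. residues from the background."""
    if length < 1:
        raise ValueError(f"length must be positive, got {length}")
    letters, probs = config._letters_probs
    seq = "".join(rng.choice(letters, size=length, p=probs))
    return Fragment(id="background", sequence=seq, label=NON_DIMER)


def plant_motif(
    fragment: Fragment,
    template: MotifTemplate,
    position: int,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
) -> Fragment:
    """Instantiate *template* at *position*, recording the interval and dimer label.

    Fixed pattern positions are written verbatim; wildcard positions are redrawn
    from the background distribution.
    """
    L = len(fragment.sequence)
    if position < 0 or position + template.length > L:
        raise ValueError(
            f"motif position {position} with length {template.length} does not fit "
            f"fragment of length {L}"
        )
    distribution = (
        config.background_distribution if config is not None else DEFAULT_BACKGROUND
    )
    letters = np.array(sorted(distribution))
    probs = np.array([distribution[a] for a in letters])
    probs = probs / probs.sum()
    chars = list(fragment.sequence)
    for offset, ch in enumerate(template.pattern):
        if ch == WILDCARD:
            chars[position + offset] = str(rng.choice(letters, p=probs))
        else:
            chars[position + offset] = ch
    return Fragment(
        id=fragment.id,
        sequence="".join(chars),
        label=DIMER,
        motif_interval=(position, position + template.length),
    )


def stratified_split(
    fragments: Sequence[Fragment],
    test_fraction: float,
    rng: np.random.Generator,
) -> tuple[list[Fragment], list[Fragment]]:
    """Class-stratified (train, test) split of a labeled fragment collection."""
    train: list[Fragment] = []
    test: list[Fragment] = []
    by_label: dict[str, list[Fragment]] = {}
    for f in fragments:
        by_label.setdefault(f.label, []).append(f)
    for group in by_label.values():
        idx = rng.permutation(len(group))
        n_test = int(round(test_fraction * len(group)))
        test += [group[i] for i in idx[:n_test]]
        train += [group[i] for i in idx[n_test:]]
    return train, test


def simulate_dataset(config: SimulationConfig) -> list[Fragment]:
    """Generate the labeled benchmark: positives with one planted motif each at a
    uniform admissible position, negatives free of exact template matches.

    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    fragments: list[Fragment] = []
    templates = list(config.motif_templates)
    width = max(4, len(str(max(config.n_positive, config.n_negative, 1))))
    for i in range(config.n_positive):
        if not templates:
            raise ValueError("cannot generate positives without motif templates")
        base = sample_background(config.fragment_length, config, rng)
        template = templates[int(rng.integers(len(templates)))]
        position = int(rng.integers(config.fragment_length - template.length + 1))
        planted = plant_motif(base, template, position, rng, config)
        fragments.append(
            Fragment(
                id=f"pos_{i:0{width}d}",
                sequence=planted.sequence,
                label=DIMER,
                motif_interval=planted.motif_interval,
            )
        )
    for i in range(config.n_negative):
        for _ in range(_MAX_REJECTIONS):
            candidate = sample_background(config.fragment_length, config, rng)
            if not any(t.regex.search(candidate.sequence) for t in templates):
                break
        else:
            raise RuntimeError(
                "rejection sampling failed: background matches templates too often"
            )
        fragments.append(
            Fragment(id=f"neg_{i:0{width}d}", sequence=candidate.sequence, label=NON_DIMER)
        )
    return fragments
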