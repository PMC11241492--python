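"""Synthetic pan-genome genotype and sensory-phenotype simulator.

Real panels of *Lactococcus lactis* strains come with three binary variant
matrices — SNPs, gene presence/absence, and intergenic-region (IGR) variants —
plus real-valued electronic-tongue and electronic-nose responses measured on
the milk each strain ferments.  This module generates data with the same
statistical skeleton: independent Bernoulli features in the three classes,
sparse planted causal features per phenotype with mixed-sign additive effects,
controllable causal-set overlap between phenotype pairs (which induces
phenotype correlation), and Gaussian noise parameterized either by a raw
standard deviation or by a target signal fraction Var(signal)/Var(y).

Features are generated independently (no linkage structure): the selection
pipeline under study never exploits linkage, and independence keeps
causal-recovery metrics unambiguous.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("SNP", "GENE", "IGR")

#: Electronic-tongue channels (Insent SA 402B convention).
TONGUE_CHANNELS = (
    "Sourness",
    "Bitterness",
    "Astringency",
    "Aftertaste-B",
    "Aftertaste-A",
    "Umami",
    "Richness",
    "Saltiness",
)

#: Electronic-nose metal-oxide sensors (Airsense PEN3 convention).
NOSE_SENSORS = ("W1C", "W5S", "W3C", "W6S", "W5C", "W1S", "W1W", "W2S", "W2W", "W3S")


@dataclass(frozen=True)
class PhenotypeSpec:
    """One simulated sensory channel.

    Parameters
    ----------
    name
        Column name in the phenotype table (e.g. ``"Umami"`` or ``"W1S"``).
    causal_indices
        Column indices (into the full concatenated feature space) of the
        planted causal features.
    effect_sizes
        Additive weight per causal feature; mixed signs are expected.
    noise_sd
        Standard deviation of the additive Gaussian noise.  Mutually
        exclusive with ``signal_fraction``.
    signal_fraction
        Target Var(signal)/Var(y) in (0, 1]; the noise standard deviation is
        resolved from the empirical signal variance at simulation time.
    """

    name: str
    causal_indices: tuple[int, ...]
    effect_sizes: tuple[float, ...]
    noise_sd: float | None = None
    signal_fraction: float | None = None

    def __post_init__(self) -> None:
        if len(self.causal_indices) != len(self.effect_sizes):
            raise ValueError(
                f"phenotype {self.name!r}: {len(self.causal_indices)} causal_indices "
                f"but {len(self.effect_sizes)} effect_sizes"
            )
        if len(set(self.causal_indices)) != len(self.causal_indices):
            raise ValueError(f"phenotype {self.name!r}: duplicate causal indices")
        if (self.noise_sd is None) == (self.signal_fraction is None):
            raise ValueError(
                f"phenotype {self.name!r}: exactly one of noise_sd / signal_fraction required"
            )
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError(f"phenotype {self.name!r}: noise_sd must be >= 0")
        if self.signal_fraction is not None and not 0 < self.signal_fraction <= 1:
            raise ValueError(f"phenotype {self.name!r}: signal_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SimDesign:
    """Full description of one simulated study.

    Defaults mirror the real panel the simulator stands in for: 194 strains
    and per-class feature counts of 107,661 SNP / 49,146 gene / 29,301 IGR
    variants.  Scaled-down designs are built by passing smaller
    ``n_features_per_class``.
    """

    n_samples: int = 194
    n_features_per_class: tuple[int, int, int] = (107661, 49146, 29301)
    presence_prob_range: tuple[float, float] = (0.1, 0.9)
    phenotype_specs: tuple[PhenotypeSpec, ...] = ()
    seed: int = 0

    @property
    def n_features(self) -> int:
        return int(sum(self.n_features_per_class))

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError(f"n_samples must be positive, got {self.n_samples}")
        if len(self.n_features_per_class) != len(FEATURE_CLASSES):
            raise ValueError("n_features_per_class must give one count per class (SNP, GENE, IGR)")
        for cls, m in zip(FEATURE_CLASSES, self.n_features_per_class):
            if m <= 0:
                raise ValueError(f"n_features_per_class[{cls}] must be positive, got {m}")
        lo, hi = self.presence_prob_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(
                f"presence_prob_range must lie strictly inside (0, 1), got {self.presence_prob_range}"
            )
        names = [s.name for s in self.phenotype_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate phenotype names")
        p = self.n_features
        for spec in self.phenotype_specs:
            for j in spec.causal_indices:
                if not 0 <= j < p:
                    raise ValueError(
                        f"phenotype {spec.name!r}: causal index {j} outside feature space of size {p}"
                    )

    def feature_ids(self) -> np.ndarray:
        """Class-prefixed stable feature identifiers, e.g. ``SNP_000001``."""
        ids: list[str] = []
        for cls, m in zip(FEATURE_CLASSES, self.n_features_per_class):
            ids.extend(f"{cls}_{i + 1:06d}" for i in range(m))
        return np.asarray(ids, dtype=object)

    def sample_ids(self) -> np.ndarray:
        return np.asarray([f"strain_{i + 1:04d}" for i in range(self.n_samples)], dtype=object)

    def overlap_matrix(self) -> pd.DataFrame:
        """Pairwise causal-set intersection counts; diagonal is the causal-set size."""
        names = [s.name for s in self.phenotype_specs]
        sets = [set(s.causal_indices) for s in self.phenotype_specs]
        k = len(names)
        out = np.zeros((k, k), dtype=int)
        for i in range(k):
            for j in range(k):
                out[i, j] = len(sets[i] & sets[j])
        return pd.DataFrame(out, index=names, columns=names)


def simulate_genotypes(design: SimDesign) -> pd.DataFrame:
    """Draw the binary samples × features matrix.

    Each feature j has its own presence probability p_j drawn uniformly from
    ``design.presence_prob_range``; entries are i.i.d. Bernoulli(p_j).
    Deterministic for a fixed design (same seed -> bitwise-identical matrix).
    """
    design.validate()
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0]))
    lo, hi = design.presence_prob_range
    n = design.n_samples
    blocks = []
    for m in design.n_features_per_class:
        p = rng.uniform(lo, hi, size=m)
        blocks.append((rng.random((n, m)) < p).astype(np.int8))
    X = np.hstack(blocks) if len(blocks) > 1 else blocks[0]
    return pd.DataFrame(X, index=design.sample_ids(), columns=design.feature_ids())


def simulate_phenotypes(G: pd.DataFrame, design: SimDesign) -> pd.DataFrame:
    """Simulate the sensory response table from a genotype matrix.

    For phenotype k: ``y_k = sum_{j in causal_k} w_kj * g_j + eps``,
    eps ~ Normal(0, sd_k^2).  With ``signal_fraction`` given, sd_k is resolved
    so that Var(signal)/Var(y) hits the target in expectation, using the
    empirical variance of the simulated signal.
    """
    design.validate()
    if G.shape[1] != design.n_features:
        raise ValueError(
            f"genotype matrix has {G.shape[1]} features but design specifies {design.n_features}"
        )
    X = G.to_numpy(dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    cols = {}
    for spec in design.phenotype_specs:
        idx = np.asarray(spec.causal_indices, dtype=int)
        if idx.size and idx.max() >= X.shape[1]:
            raise ValueError(f"phenotype {spec.name!r}: causal index {idx.max()} absent from G")
        w = np.asarray(spec.effect_sizes, dtype=float)
        signal = X[:, idx] @ w if idx.size else np.zeros(n)
        if spec.signal_fraction is not None:
            f = spec.signal_fraction
            var_sig = float(np.var(signal))
            sd = float(np.sqrt(var_sig * (1.0 - f) / f))
        else:
            sd = float(spec.noise_sd)
        cols[spec.name] = signal + sd * rng.standard_normal(n)
    return pd.DataFrame(cols, index=G.index)


def _allocate_causal_sets(
    n_features: int,
    n_phenotypes: int,
    n_causal: int,
    overlaps: Mapping[tuple[int, int], int],
    rng: np.random.Generator,
) -> list[list[int]]:
    """Allocate causal index sets with exact planted pairwise overlaps.

    Each overlapping pair gets a dedicated disjoint pool of shared features;
    the remainder of each causal set is filled with features unique to that
    phenotype, so |set_i ∩ set_j| equals the requested overlap exactly.
    """
    per_pheno_shared = np.zeros(n_phenotypes, dtype=int)
    for (i, j), o in overlaps.items():
        if not (0 <= i < j < n_phenotypes):
            raise ValueError(f"overlap pair {(i, j)} out of range or not ordered i < j")
        if o < 0:
            raise ValueError(f"negative overlap for pair {(i, j)}")
        per_pheno_shared[i] += o
        per_pheno_shared[j] += o
    if (per_pheno_shared > n_causal).any():
        raise ValueError("requested overlaps exceed the causal-set size of some phenotype")
    total = sum(o for o in overlaps.values()) + int(
        np.sum(n_causal - per_pheno_shared)
    )
    if total > n_features:
        raise ValueError(
            f"need {total} distinct causal features but the design only has {n_features}"
        )
    pool = rng.choice(n_features, size=total, replace=False)
    cursor = 0
    sets: list[list[int]] = [[] for _ in range(n_phenotypes)]
    for (i, j), o in overlaps.items():
        shared = pool[cursor : cursor + o]
        cursor += o
        sets[i].extend(shared.tolist())
        sets[j].extend(shared.tolist())
    for k in range(n_phenotypes):
        fill = n_causal - len(sets[k])
        sets[k].extend(pool[cursor : cursor + fill].tolist())
        cursor += fill
    return sets


def planted_overlap_design(
    n_samples: int = 194,
    n_features_per_class: tuple[int, int, int] = (107661, 49146, 29301),
    names: Sequence[str] = TONGUE_CHANNELS,
    n_causal: int = 20,
    overlaps: Mapping[tuple[int, int], int] | None = None,
    signal_fraction: float = 0.9,
    effect_size_range: tuple[float, float] = (0.5, 1.5),
    seed: int = 0,
) -> SimDesign:
    """Build a design whose phenotype pairs share exactly the planted overlaps.

    Effect sizes are drawn with magnitude Uniform(*effect_size_range*) and a
    random sign, so that signed importance propagation is exercised.  Each
    causal feature carries **one** weight shared by every phenotype it
    appears in: a genetic factor pushes related phenotypes in a consistent
    direction, which is what makes planted causal overlap translate into
    phenotype correlation.  Noise is parameterized by ``signal_fraction``
    (default 0.9), mirroring the high cross-validated R² regime the method
    targets.
    """
    if overlaps is None:
        overlaps = {}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n_features = int(sum(n_features_per_class))
    sets = _allocate_causal_sets(n_features, len(names), n_causal, overlaps, rng)
    lo, hi = effect_size_range
    weights: dict[int, float] = {}
    for causal in sets:
        for j in causal:
            if j not in weights:
                weights[j] = float(
                    rng.uniform(lo, hi) * (rng.integers(0, 2) * 2 - 1)
                )
    specs = []
    for name, causal in zip(names, sets):
        specs.append(
            PhenotypeSpec(
                name=name,
                causal_indices=tuple(int(c) for c in causal),
                effect_sizes=tuple(weights[int(c)] for c in causal),
                signal_fraction=signal_fraction,
            )
        )
    return SimDesign(
        n_samples=n_samples,
        n_features_per_class=tuple(n_features_per_class),
        phenotype_specs=tuple(specs),
        seed=seed,
    )


def block_overlap_design(
    n_samples: int = 194,
    n_features_per_class: tuple[int, int, int] = (107661, 49146, 29301),
    n_phenotypes: int = 8,
    n_causal: int = 20,
    signal_fraction: float = 0.9,
    seed: int = 0,
) -> SimDesign:
    """Default eight-channel design with a block overlap gradient.

    Consecutive phenotype pairs share 75% / 25% / 0% of their causal features
    (cycling), emulating the observed gradient from strongly correlated sensor
    pairs with many jointly selected features down to uncorrelated pairs with
    none.
    """
    if n_phenotypes % 2:
        raise ValueError("n_phenotypes must be even for the block pair design")
    names = list(TONGUE_CHANNELS[:n_phenotypes])
    if len(names) < n_phenotypes:
        names += [f"pheno_{k}" for k in range(len(names), n_phenotypes)]
    fracs = (0.75, 0.25, 0.0)
    overlaps = {}
    for pair_idx in range(n_phenotypes // 2):
        o = int(round(fracs[pair_idx % 3] * n_causal))
        if o:
            overlaps[(2 * pair_idx, 2 * pair_idx + 1)] = o
    return planted_overlap_design(
        n_samples=n_samples,
        n_features_per_class=n_features_per_class,
        names=names,
        n_causal=n_causal,
        overlaps=overlaps,
        signal_fraction=signal_fraction,
        seed=seed,
    )


def trend_design(
    n_samples: int = 194,
    n_features_per_class: tuple[int, int, int] = (300, 200, 100),
    n_causal: int = 40,
    overlaps: Mapping[tuple[int, int], int] | None = None,
    signal_fraction: float = 0.9,
    seed: int = 0,
) -> SimDesign:
    """Four-phenotype design with planted pairwise overlaps {0, 10, 30}.

    Used for checking that higher causal overlap produces both higher
    phenotype correlation and more jointly selected features.
    """
    if overlaps is None:
        overlaps = {(0, 1): 30, (2, 3): 10}
    return planted_overlap_design(
        n_samples=n_samples,
        n_features_per_class=n_features_per_class,
        names=("P1", "P2", "P3", "P4"),
        n_causal=n_causal,
        overlaps=overlaps,
        signal_fraction=signal_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# design (de)serialization


def design_to_dict(design: SimDesign) -> dict:
    d = dataclasses.asdict(design)
    d["phenotype_specs"] = [dataclasses.asdict(s) for s in design.phenotype_specs]
    return d


def design_from_dict(d: Mapping) -> SimDesign:
    specs = tuple(
        PhenotypeSpec(
            name=s["name"],
            causal_indices=tuple(s["causal_indices"]),
            effect_sizes=tuple(s["effect_sizes"]),
            noise_sd=s.get("noise_sd"),
            signal_fraction=s.get("signal_fraction"),
        )
        for s in d.get("phenotype_specs", ())
    )
    return SimDesign(
        n_samples=int(d["n_samples"]),
        n_features_per_class=tuple(d["n_features_per_class"]),
        presence_prob_range=tuple(d.get("presence_prob_range", (0.1, 0.9))),
        phenotype_specs=specs,
        seed=int(d.get("seed", 0)),
    )


def save_design(design: SimDesign, path) -> None:
    with open(path, "w") as fh:
        json.dump(design_to_dict(design), fh, indent=1)


def load_design(path) -> SimDesign:
    with open(path) as fh:
        return design_from_dict(json.load(fh))
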