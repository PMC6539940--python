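"""Activity labelling rules and synthetic fixtures.

Two responsibilities live here. First, the bioactivity bookkeeping used to
turn raw assay values (IC50, EC50, Ki, Kd … on the molar scale) into binary
activity labels: the p-bioactivity is −log10 of the raw value, repeated
measurements are averaged on the log scale, actives are labelled +1 and a
deliberately smaller inactive set (~30% of the actives by default) is
sampled to mirror the class imbalance of receptor–ligand screening data.

Second, seeded synthetic generators: toy molecules of two geometrically
distinct classes (compact blobs vs. elongated rods) that the shape
descriptor separates by construction, and feature tables with known
mutual-information structure for exercising the selection and
classification stages. The shape classes make no claim to imitate real
ligand chemistry — they are the separability fixture for the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import Atom, Molecule, vdw_radius
from .featsel import FeatureTable

#: Span of p-bioactivity values emulated for synthetic actives.
ACTIVITY_RANGE = (-12.0, 4.0)

#: Default inactive-to-active ratio of the labelled sets.
DEFAULT_INACTIVE_RATIO = 0.3


def p_bioactivity(raw_values, log_scale_mean: bool = True) -> float:
    """Aggregate raw assay values into one p-bioactivity = −log10(val).

    Multiple measurements are averaged on the log scale by default
    (``mean of −log10 values``); set ``log_scale_mean=False`` to average the
    raw values before taking the log.
    """
    vals = np.asarray(list(raw_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no raw bioactivity values given")
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise ValueError("raw bioactivity values must be positive and finite")
    if log_scale_mean:
        return float(np.mean(-np.log10(vals)))
    return float(-np.log10(np.mean(vals)))


@dataclass(frozen=True)
class BioactivityRecord:
    """One molecule's assay history collapsed to a p-bioactivity value."""

    molecule_id: str
    raw_values: tuple[float, ...]

    @property
    def p_bioactivity(self) -> float:
        return p_bioactivity(self.raw_values)


@dataclass(frozen=True)
class LabelledSet:
    """Items with ±1 labels, provenance tag and the seed that produced it."""

    items: tuple
    labels: np.ndarray
    provenance: str
    seed: int

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if len(labels) != len(self.items):
            raise ValueError("one label per item")
        if len(np.unique(labels)) < 2:
            raise ValueError("both classes must be present")
        object.__setattr__(self, "labels", labels)

    @property
    def n_active(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_inactive(self) -> int:
        return int(np.sum(self.labels == -1))


def build_labelled_set(actives, inactive_pool, ratio: float = DEFAULT_INACTIVE_RATIO,
                       seed: int = 0, low_activity_threshold: float | None = None,
                       activities=None, provenance: str = "real") -> LabelledSet:
    """Label actives +1 and sample an imbalanced −1 class from a pool.

    ``round(ratio·|actives|)`` inactives are drawn uniformly without
    replacement (seeded). When ``low_activity_threshold`` is given (the
    exploratory variant; off by default because mixing weakly active
    compounds into the inactive class degrades the labels), actives whose
    p-bioactivity in ``activities`` falls below the threshold are moved to
    the inactive class instead.
    """
    actives = list(actives)
    inactive_pool = list(inactive_pool)
    n_inactive = round(ratio * len(actives))
    if len(inactive_pool) < n_inactive:
        raise ValueError(
            f"inactive pool ({len(inactive_pool)}) smaller than required "
            f"{n_inactive}")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(inactive_pool), size=n_inactive, replace=False)
    items = list(actives) + [inactive_pool[i] for i in picked]
    labels = np.array([1] * len(actives) + [-1] * n_inactive)
    if low_activity_threshold is not None:
        if activities is None:
            raise ValueError("low-activity rule needs per-active activities")
        acts = np.asarray(list(activities), dtype=float)
        labels[:len(actives)][acts < low_activity_threshold] = -1
    return LabelledSet(items=tuple(items), labels=labels,
                       provenance=provenance, seed=seed)


# ---------------------------------------------------------------------------
# Synthetic molecules


def make_toy_molecule(shape_class: str, n_atoms: int = 12, noise: float = 0.1,
                      seed: int = 0, element: str = "C") -> Molecule:
    """Deterministic toy molecule of a given shape class.

    ``compact`` scatters atoms around a dense cluster (Gaussian cloud of
    ~1.5 Å spread); ``elongated`` spaces them 1.5 Å apart along the z axis.
    Coordinates get isotropic Gaussian jitter of scale ``noise`` (Å).
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be at least 1")
    rng = np.random.default_rng(seed)
    if shape_class == "compact":
        coords = rng.normal(0.0, 1.5, size=(n_atoms, 3))
    elif shape_class == "elongated":
        z = 1.5 * (np.arange(n_atoms) - (n_atoms - 1) / 2.0)
        coords = np.column_stack([np.zeros(n_atoms), np.zeros(n_atoms), z])
    else:
        raise ValueError(f"unknown shape_class {shape_class!r}")
    coords = coords + rng.normal(0.0, noise, size=coords.shape)
    r = vdw_radius(element)
    atoms = tuple(Atom(element=element, coords=c, vdw_radius=r) for c in coords)
    return Molecule(id=f"{shape_class}-{seed}", atoms=atoms)


def make_benchmark(n_active: int = 100, ratio: float = DEFAULT_INACTIVE_RATIO,
                   noise: float = 0.1, n_atoms: int = 12,
                   seed: int = 0) -> LabelledSet:
    """Shape-separable benchmark: compact actives vs. elongated inactives.

    Produces ``n_active + round(ratio·n_active)`` molecules with the
    configured class imbalance. Actives carry a synthetic p-bioactivity
    drawn uniformly over the emulated activity span ``ACTIVITY_RANGE``.
    """
    if n_active < 10:
        raise ValueError("n_active must be at least 10")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=2 * n_active + n_active)
    actives = []
    for i in range(n_active):
        m = make_toy_molecule("compact", n_atoms=n_atoms, noise=noise,
                              seed=int(child_seeds[i]))
        act = float(rng.uniform(*ACTIVITY_RANGE))
        actives.append(Molecule(id=f"active-{i}", atoms=m.atoms, activity=act))
    n_inactive = round(ratio * n_active)
    pool = []
    for i in range(2 * n_inactive if n_inactive else 1):
        m = make_toy_molecule("elongated", n_atoms=n_atoms, noise=noise,
                              seed=int(child_seeds[n_active + i]))
        pool.append(Molecule(id=f"inactive-{i}", atoms=m.atoms))
    return build_labelled_set(actives, pool, ratio=ratio, seed=seed,
                              provenance="synthetic")


def make_feature_table(n: int, d: int, structure: str = "separable",
                       seed: int = 0) -> FeatureTable:
    """Feature tables with known mutual-information structure.

    ``separable``
        Feature 0 carries the label signal (class-shifted Gaussian), the
        rest are independent noise.
    ``redundant-pair``
        Feature 0 is a noisy copy of the label, feature 1 duplicates
        feature 0 exactly, the rest are independent noise.
    ``noise``
        All features independent of the label.
    """
    if n < 4 or d < 1:
        raise ValueError("need n ≥ 4 and d ≥ 1")
    rng = np.random.default_rng(seed)
    y = np.where(np.arange(n) % 2 == 0, 1, -1)
    rng.shuffle(y)
    X = rng.normal(size=(n, d))
    if structure == "separable":
        X[:, 0] = y * 2.0 + rng.normal(0.0, 0.5, size=n)
    elif structure == "redundant-pair":
        if d < 2:
            raise ValueError("redundant-pair needs d ≥ 2")
        X[:, 0] = y * 2.0 + rng.normal(0.0, 0.5, size=n)
        X[:, 1] = X[:, 0]
    elif structure != "noise":
        raise ValueError(f"unknown structure {structure!r}")
    names = tuple(f"f{j}" for j in range(d))
    return FeatureTable(matrix=X, feature_names=names, labels=y)
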