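"""The five-component weighted similarity score.

Half of the total comes from a GDT-style C-alpha component: the mean, over
the thresholds 0.5/1/2/4 Angstrom, of the fraction of native residues whose
C-alpha lies within the threshold under the best superposition found for it.
The other half comes from four side-chain terms measured under the single
C-alpha reference superposition: the centroid-distance term and the three
orientation-angle terms, each scored by linearly-decaying weights over
cumulative bins,

    score = 2 * sum_i (k - i + 1) * p_i / (k * (k + 1)),

where p_i is the fraction of residues falling in cumulative bin i of k.
A residue in the first bin is in every bin and contributes full weight; one
beyond the last bin contributes nothing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structure_io import Structure, pair_residues
from .superposition import SuperpositionResult, gdt_search
from .united_residue import pair_geometry, to_united_residue

__all__ = [
    "SpecsConfig",
    "SpecsComponents",
    "NormalizationError",
    "score_dca",
    "score_rsc",
    "score_planar",
    "score_dihedral",
    "specs_total",
    "evaluate",
]


class NormalizationError(ValueError):
    """Raised when a score would be normalized by a zero count."""


def _deg(values: Sequence[float]) -> tuple[float, ...]:
    return tuple(math.radians(v) for v in values)


@dataclass(frozen=True)
class SpecsConfig:
    """Thresholds, bin edges and weights of the score.

    ``dihedral_bins`` uses a uniform 30-degree progression up to 300; pass
    ``dihedral_bin7=201`` to reproduce the alternative 7th edge.
    """

    ca_thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    sc_bin_width: float = 0.5
    k_sc: int = 10
    planar_bins_deg: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0)
    dihedral_bins_deg: tuple[float, ...] = (
        30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0, 270.0, 300.0
    )
    ca_weight: float = 4.0
    total_weight: float = 8.0

    def __post_init__(self) -> None:
        for name in ("ca_thresholds", "planar_bins_deg", "dihedral_bins_deg"):
            edges = getattr(self, name)
            if any(b >= a for b, a in zip(edges, edges[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.ca_weight <= 0 or self.total_weight <= 0:
            raise ValueError("weights must be positive")

    @classmethod
    def with_dihedral_bin7(cls, bin7: float) -> "SpecsConfig":
        bins = [30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0, 270.0, 300.0]
        bins[6] = float(bin7)
        return cls(dihedral_bins_deg=tuple(bins))

    @property
    def sc_bins(self) -> tuple[float, ...]:
        return tuple(self.sc_bin_width * i for i in range(1, self.k_sc + 1))

    @property
    def planar_bins_rad(self) -> tuple[float, ...]:
        return _deg(self.planar_bins_deg)

    @property
    def dihedral_bins_rad(self) -> tuple[float, ...]:
        return _deg(self.dihedral_bins_deg)


@dataclass
class SpecsComponents:
    """The five component scores, the weighted total and the bin profiles.

    Side-chain components are ``None`` (and the total falls back to the
    C-alpha component) only for the degenerate case of a native with no
    side-chain-bearing residue.
    """

    dca: float
    rsc: float | None
    theta1: float | None
    theta2: float | None
    phi: float | None
    total: float
    n_pairs: int
    n_native: int
    n_native_sc: int
    bin_profiles: dict[str, tuple[float, ...]] = field(default_factory=dict)
    reference: SuperpositionResult | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def sc_defined(self) -> bool:
        return self.rsc is not None

    def as_dict(self) -> dict:
        return {
            "dca": self.dca,
            "rsc": self.rsc,
            "theta1": self.theta1,
            "theta2": self.theta2,
            "phi": self.phi,
            "total": self.total,
            "n_pairs": self.n_pairs,
            "n_native": self.n_native,
            "n_native_sc": self.n_native_sc,
            "bin_profiles": {k: list(v) for k, v in self.bin_profiles.items()},
            "warnings": list(self.warnings),
        }


def _cumulative_score(
    values: Sequence[float], edges: Sequence[float], n_norm: int
) -> tuple[float, tuple[float, ...]]:
    """Linearly-weighted cumulative-bin score and the bin-occupancy profile."""
    if n_norm <= 0:
        raise NormalizationError("normalization count must be >= 1")
    values = np.asarray(values, dtype=float)
    k = len(edges)
    profile = tuple(
        float(np.count_nonzero(values <= edge)) / n_norm for edge in edges
    )
    weighted = sum((k - i) * p for i, p in enumerate(profile))
    return 2.0 * weighted / (k * (k + 1)), profile


def score_dca(
    max_counts: dict[float, int] | Sequence[int],
    n_native: int,
    thresholds: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
) -> tuple[float, tuple[float, ...]]:
    """Mean fraction of native residues within each C-alpha threshold.

    *max_counts* maps threshold -> best superimposable count (or gives the
    counts in threshold order).
    """
    if n_native <= 0:
        raise NormalizationError("n_native must be >= 1")
    if isinstance(max_counts, dict):
        counts = [max_counts[float(t)] for t in thresholds]
    else:
        counts = list(max_counts)
        if len(counts) != len(thresholds):
            raise ValueError("one count per threshold required")
    profile = tuple(c / n_native for c in counts)
    return sum(profile) / len(profile), profile


def score_rsc(
    r_values: Sequence[float], n_sc: int, config: SpecsConfig = SpecsConfig()
) -> tuple[float, tuple[float, ...]]:
    """Side-chain centroid distance component over cumulative 0.5 A bins."""
    return _cumulative_score(r_values, config.sc_bins, n_sc)


def score_planar(
    angles: Sequence[float], n_sc: int, config: SpecsConfig = SpecsConfig()
) -> tuple[float, tuple[float, ...]]:
    """Planar-angle component; *angles* in radians."""
    return _cumulative_score(angles, config.planar_bins_rad, n_sc)


def score_dihedral(
    angles: Sequence[float], n_sc: int, config: SpecsConfig = SpecsConfig()
) -> tuple[float, tuple[float, ...]]:
    """Dihedral-angle component; *angles* in radians within [0, 2*pi)."""
    return _cumulative_score(angles, config.dihedral_bins_rad, n_sc)


def specs_total(
    dca: float,
    rsc: float,
    theta1: float,
    theta2: float,
    phi: float,
    config: SpecsConfig = SpecsConfig(),
) -> float:
    """Weighted combination: (4*dca + rsc + theta1 + theta2 + phi) / 8."""
    for name, value in (("dca", dca), ("rsc", rsc), ("theta1", theta1),
                        ("theta2", theta2), ("phi", phi)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"component {name}={value} outside [0, 1]")
    return (config.ca_weight * dca + rsc + theta1 + theta2 + phi) / config.total_weight


def evaluate(
    model: Structure,
    native: Structure,
    config: SpecsConfig = SpecsConfig(),
) -> SpecsComponents:
    """Score *model* against *native* end to end.

    Residues are paired by identifier, the GDT-style search is run on the
    paired C-alpha coordinates, and the side-chain terms are measured under
    the single reference superposition it selects.  The C-alpha component is
    normalized by the native length; the side-chain components by the number
    of native residues bearing at least one side-chain heavy atom (pairs
    whose model side-chain is missing count against the score).
    """
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        correspondence = pair_residues(model, native)
    notes.extend(str(w.message) for w in caught)

    ur_model = {i: to_united_residue(model.residues[i]) for i, _ in correspondence.pairs}
    ur_native = {j: to_united_residue(native.residues[j]) for _, j in correspondence.pairs}

    model_ca = np.asarray([ur_model[i].ca for i, _ in correspondence.pairs])
    native_ca = np.asarray([ur_native[j].ca for _, j in correspondence.pairs])

    max_counts, reference = gdt_search(model_ca, native_ca, config.ca_thresholds)
    dca, dca_profile = score_dca(max_counts, correspondence.n_native, config.ca_thresholds)

    r_values: list[float] = []
    theta1_values: list[float] = []
    theta2_values: list[float] = []
    phi_values: list[float] = []
    for i, j in correspondence.pairs:
        m, n = ur_model[i], ur_native[j]
        if not (m.has_distinct_sc and n.has_distinct_sc):
            if n.has_distinct_sc and not m.has_distinct_sc:
                notes.append(
                    f"model residue {model.residues[i].id} lacks side-chain atoms; "
                    "pair counted as a miss"
                )
            continue
        geom = pair_geometry(m, n, reference.transform)
        r_values.append(geom.r)
        theta1_values.append(geom.theta1)
        theta2_values.append(geom.theta2)
        phi_values.append(geom.phi)

    profiles: dict[str, tuple[float, ...]] = {"dca": dca_profile}
    n_sc = correspondence.n_native_sc
    if n_sc == 0:
        notes.append("native has no side-chain-bearing residue; side-chain "
                     "components undefined, total equals the C-alpha component")
        return SpecsComponents(
            dca=dca, rsc=None, theta1=None, theta2=None, phi=None, total=dca,
            n_pairs=len(correspondence), n_native=correspondence.n_native,
            n_native_sc=0, bin_profiles=profiles, reference=reference, warnings=notes,
        )

    rsc, profiles["rsc"] = score_rsc(r_values, n_sc, config)
    theta1, profiles["theta1"] = score_planar(theta1_values, n_sc, config)
    theta2, profiles["theta2"] = score_planar(theta2_values, n_sc, config)
    phi, profiles["phi"] = score_dihedral(phi_values, n_sc, config)
    total = specs_total(dca, rsc, theta1, theta2, phi, config)

    return SpecsComponents(
        dca=dca, rsc=rsc, theta1=theta1, theta2=theta2, phi=phi, total=total,
        n_pairs=len(correspondence), n_native=correspondence.n_native,
        n_native_sc=n_sc, bin_profiles=profiles, reference=reference, warnings=notes,
    )
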