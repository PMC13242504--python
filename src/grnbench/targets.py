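"""Target statistics that the topology generator and sign optimizer fit.

The benchmark construction is driven by empirical summary statistics of
real gene regulatory network models: a power-law out-degree distribution,
an approximately Poisson in-degree distribution, the relative frequencies
of the 15 feed-forward-loop cluster motifs, and — per biological kingdom —
the distribution of the 8 signed FFL types, the fraction of positive
feedback loops by cycle length, and the fraction of activating inputs by
in-degree.

The numeric values of the kingdom-specific vectors come from meta-analytic
estimates that users supply through configuration.  The defaults shipped
here are fixed illustrative stand-ins chosen from qualitative regularities
(the all-activating coherent FFL type dominates, feedback loops are
enriched for inhibitory edges, the activator fraction decreases with
in-degree); see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

_TOL = 1e-9

KINGDOMS = ("animal", "bacteria", "fungi", "plant")

N_FFL_TYPES = 8
N_CLUSTER_MOTIFS = 15
MAX_FBL_LEN = 6


def _check_freq(name: str, vec, length: int | None = None) -> tuple[float, ...]:
    t = tuple(float(x) for x in vec)
    if length is not None and len(t) != length:
        raise ValueError(f"{name} must have {length} bins, got {len(t)}")
    if any(x < 0 for x in t):
        raise ValueError(f"{name} has negative entries")
    if abs(sum(t) - 1.0) > _TOL:
        raise ValueError(f"{name} must sum to 1 (got {sum(t)!r})")
    return t


def _check_frac(name: str, x: float) -> float:
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")
    return x


_DEFAULT_CLUSTER_FREQ = (
    # motifs 1-6: two FFLs sharing one node (dominant in sparse networks)
    0.16, 0.13, 0.11, 0.09, 0.07, 0.06,
    # motifs 7-12: two FFLs sharing an edge
    0.08, 0.07, 0.06, 0.05, 0.04, 0.03,
    # motifs 13-15: clusters on a single 3-node set (rare, dense)
    0.02, 0.02, 0.01,
)

_DEFAULT_FFL_TYPE_FREQ = {
    # types 1-4 coherent (type 1 = all-activating), 5-8 incoherent
    "animal": (0.32, 0.08, 0.06, 0.10, 0.18, 0.12, 0.08, 0.06),
    "bacteria": (0.40, 0.06, 0.05, 0.09, 0.22, 0.08, 0.06, 0.04),
    "fungi": (0.30, 0.10, 0.07, 0.08, 0.20, 0.10, 0.09, 0.06),
    "plant": (0.35, 0.09, 0.06, 0.08, 0.17, 0.11, 0.08, 0.06),
}

_DEFAULT_FBL_POSITIVE_FRAC = {
    # fraction of positive feedback loops, cycle lengths 1..6
    "animal": (0.70, 0.45, 0.40, 0.35, 0.30, 0.30),
    "bacteria": (0.60, 0.40, 0.35, 0.30, 0.30, 0.25),
    "fungi": (0.65, 0.45, 0.40, 0.35, 0.30, 0.30),
    "plant": (0.70, 0.50, 0.40, 0.35, 0.35, 0.30),
}

_DEFAULT_POS_INPUT_FRAC = {
    # fraction of activating inputs among regulators, by in-degree
    "animal": {1: 0.75, 2: 0.70, 3: 0.65, 4: 0.60, 5: 0.55, 6: 0.50},
    "bacteria": {1: 0.80, 2: 0.72, 3: 0.66, 4: 0.60, 5: 0.55, 6: 0.52},
    "fungi": {1: 0.72, 2: 0.68, 3: 0.62, 4: 0.58, 5: 0.54, 6: 0.50},
    "plant": {1: 0.78, 2: 0.70, 3: 0.64, 4: 0.60, 5: 0.56, 6: 0.52},
}


@dataclass(frozen=True)
class TargetDistributions:
    """All empirical target statistics the generator and optimizer fit.

    Parameters
    ----------
    gamma
        Exponent of the out-degree power law ``P(k) ~ k**-gamma``; > 1.
    k_out_min
        Minimum out-degree of the power-law support.
    poisson_rate
        Rate of the Poisson in-degree target.  The literature does not pin
        this down; the mean connectivity is the natural default.
    mean_connectivity
        Target average connectivity ``<k> = |E| / n``.
    n_external
        Target number of external-parameter nodes (in-degree 0).
    ffl_cluster_freq
        Relative frequency of cluster motifs 1-15 (kingdom-independent).
    ffl_type_freq
        Per kingdom, relative frequency of signed FFL types 1-8.
    fbl_positive_frac
        Per kingdom, fraction of positive feedback loops for lengths 1-6.
    pos_input_frac
        Per kingdom, fraction of activating inputs by in-degree.
    """

    gamma: float = 2.0
    k_out_min: int = 1
    poisson_rate: float = 2.5
    mean_connectivity: float = 2.5
    n_external: int = 1
    ffl_cluster_freq: tuple[float, ...] = _DEFAULT_CLUSTER_FREQ
    ffl_type_freq: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_FFL_TYPE_FREQ)
    )
    fbl_positive_frac: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_FBL_POSITIVE_FRAC)
    )
    pos_input_frac: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_POS_INPUT_FRAC.items()}
    )

    def __post_init__(self) -> None:
        if not self.gamma > 1:
            raise ValueError(f"gamma must exceed 1, got {self.gamma!r}")
        if self.k_out_min < 0:
            raise ValueError("k_out_min must be nonnegative")
        if self.poisson_rate < 0:
            raise ValueError("poisson_rate must be nonnegative")
        if self.n_external < 0:
            raise ValueError("n_external must be nonnegative")
        _check_freq("ffl_cluster_freq", self.ffl_cluster_freq, N_CLUSTER_MOTIFS)
        for kingdom, vec in self.ffl_type_freq.items():
            object.__setattr__(
                self,
                "ffl_type_freq",
                {**dict(self.ffl_type_freq), kingdom: _check_freq(
                    f"ffl_type_freq[{kingdom}]", vec, N_FFL_TYPES)},
            )
        for kingdom, vec in self.fbl_positive_frac.items():
            t = tuple(
                _check_frac(f"fbl_positive_frac[{kingdom}][{i}]", x)
                for i, x in enumerate(vec)
            )
            if len(t) != MAX_FBL_LEN:
                raise ValueError(
                    f"fbl_positive_frac[{kingdom}] needs {MAX_FBL_LEN} entries"
                )
            object.__setattr__(
                self,
                "fbl_positive_frac",
                {**dict(self.fbl_positive_frac), kingdom: t},
            )
        for kingdom, m in self.pos_input_frac.items():
            for k, x in m.items():
                _check_frac(f"pos_input_frac[{kingdom}][{k}]", x)

    def kingdoms(self) -> tuple[str, ...]:
        return tuple(self.ffl_type_freq)

    def pos_input_target(self, kingdom: str, in_degree: int) -> float:
        """Target activator fraction for a given in-degree.

        In-degrees beyond the tabulated range use the largest tabulated
        bin (the empirical curves flatten at high in-degree).
        """
        m = self.pos_input_frac[kingdom]
        if in_degree in m:
            return m[in_degree]
        return m[max(m)]


def default_targets() -> TargetDistributions:
    return TargetDistributions()
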