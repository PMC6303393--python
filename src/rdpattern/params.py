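"""Kinetic and diffusion parameters of the Nodal-Lefty activator-inhibitor models.

The two species are Nodal (N), a short-range self-activating ligand, and
Lefty (L), its long-range inhibitor. Units are fixed throughout the package:
concentration in nM, time in min, length in um. The default parameter set is
the measured/estimated set for the synthetic HEK293 circuit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import yaml

__all__ = ["ModelKind", "ModelParameters", "load_parameters", "save_parameters"]


class ModelKind(str, Enum):
    """Which inhibition mechanism Lefty uses.

    ``competitive``: Lefty competes with Nodal for receptors/co-receptor only.
    ``competitive_plus_direct``: in addition, Lefty binds Nodal directly and
    removes both species at rate ``k_plus * N * L``. The competitive model is
    the special case ``k_plus = 0``.
    """

    COMPETITIVE = "competitive"
    COMPETITIVE_PLUS_DIRECT = "competitive_plus_direct"


@dataclass(frozen=True)
class ModelParameters:
    """All kinetic/diffusion constants of the two reaction-diffusion models.

    Attributes
    ----------
    alpha_N, alpha_L : float
        Maximum production rates of Nodal and Lefty (nM min^-1).
    n_N, n_L : float
        Hill coefficients of activation by Nodal and inhibition by Lefty.
    K_N, K_L : float
        Dissociation coefficients of Nodal and Lefty (nM).
    gamma_N, gamma_L : float
        First-order degradation rates (min^-1).
    D_N, D_L : float
        Diffusion coefficients (um^2 min^-1).
    k_plus : float
        Nodal-Lefty association rate (min^-1 nM^-1); only enters the
        direct-inhibition model.
    """

    alpha_N: float = 4.0
    alpha_L: float = 4.0
    n_N: float = 2.63
    n_L: float = 1.09
    K_N: float = 9.28
    K_L: float = 14.96
    gamma_N: float = 2.37e-3
    gamma_L: float = 5.65e-3
    D_N: float = 1.96
    D_L: float = 56.39
    k_plus: float = 0.03

    def __post_init__(self) -> None:
        for name in ("alpha_N", "alpha_L", "k_plus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("K_N", "K_L", "n_N", "n_L", "gamma_N", "gamma_L", "D_N", "D_L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    @property
    def diffusion_ratio(self) -> float:
        """d = D_L / D_N, the ratio entering the Turing inequalities."""
        return self.D_L / self.D_N

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


_PARAM_KEYS = [f.name for f in dataclasses.fields(ModelParameters)]


def save_parameters(path: str | Path, p: ModelParameters, kind: ModelKind) -> None:
    """Write a flat key-value parameter file (YAML mapping).

    Keys are exactly the ``ModelParameters`` field names plus ``model``.
    """
    data = {k: float(v) for k, v in p.to_dict().items()}
    data["model"] = kind.value
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_parameters(path: str | Path) -> tuple[ModelParameters, ModelKind]:
    """Read a flat key-value parameter file written by :func:`save_parameters`."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} is not a flat key-value mapping")
    kind = ModelKind(data.pop("model", ModelKind.COMPETITIVE.value))
    unknown = set(data) - set(_PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParameters(**{k: float(v) for k, v in data.items()}), kind
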