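"""Model parameterization.

The leading-edge model tracks six dimensionless densities — nascent adhesions
(``n``), stable adhesions (``s``), recruited myosin (``m``), phospho-paxillin-
bearing nascent adhesions (``x``), active Rac (``r``) and active-PAK-bearing
complexes (``p``) — plus the derived dimensionless protrusion velocity ``v``.

Parameters follow the field's naming scheme: first-order rate constants
``k_a,i`` / ``k_d,i`` (min^-1) for assembly/activation and disassembly/
deactivation of species *i*, dimensionless gains classified as enhancement
(``E_s``), inhibition (``I_n``) or consumption-augmentation (``C_s``)
parameters, dimensionless ratios ``K_i = k_a,i / k_d,i``, and the ECM coupling
parameter ``k_ecm`` (min^-1), a monotone but not necessarily linear function
of extracellular-matrix density.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["ModelParameters", "ScalingSpec", "base_case", "load_parameters", "save_parameters"]

_SPECIES = ("n", "s", "m", "x", "r", "p")
_REL_TOL = 1e-12


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants, feedback gains and scaling constants of the model.

    Attributes
    ----------
    k_ecm : float
        ECM coupling parameter (min^-1) multiplying the v-proportional
        nascent-adhesion formation rate.
    E_s : float
        Gain of the myosin -> adhesion-maturation feedback, f(m) = 1 + E_s*m.
    I_n : float
        Gain of stable-adhesion inhibition of protrusion, g(s) = 1 + I_n*s.
    C_s : float
        Convective-removal coefficient for stable adhesions; the stable
        adhesion sink is k_d,s * (1 + C_s*v) * s.
    rate_constants : mapping
        species -> {"k_a": float, "k_d": float} in min^-1.  Species ``n`` only
        carries ``k_d`` (the v-coupled turnover coefficient); its source is
        k_ecm * v.
    p0 : float
        Basal paxillin phosphorylation activity; lets the signaling variables
        evolve once nascent adhesions exist.
    v0 : float
        Basal (Rac-independent) protrusion drive; lets the system leave the
        all-zero state, since nascent-adhesion formation is proportional to v.
    D_r : float
        Diffusion coefficient of active Rac (um^2/min); used only by the
        spatial simulator.
    """

    k_ecm: float = 0.1
    E_s: float = 0.0
    I_n: float = 0.0
    C_s: float = 10.0
    rate_constants: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    p0: float = 0.005
    v0: float = 0.01
    D_r: float = 15.0

    def __post_init__(self) -> None:
        for name in ("k_ecm", "E_s", "I_n", "C_s", "p0", "v0", "D_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        for sp, kk in self.rate_constants.items():
            if sp not in _SPECIES:
                raise ValueError(f"unknown species {sp!r} in rate_constants")
            for key, val in kk.items():
                if key not in ("k_a", "k_d"):
                    raise ValueError(f"unknown rate-constant key {key!r} for species {sp!r}")
                if val < 0:
                    raise ValueError(f"rate constant {key} for {sp!r} must be >= 0")

    # -- convenience accessors -------------------------------------------------
    def k_a(self, species: str) -> float:
        return float(self.rate_constants[species]["k_a"])

    def k_d(self, species: str) -> float:
        return float(self.rate_constants[species]["k_d"])

    @property
    def K_ratios(self) -> dict[str, float]:
        """K_i = k_a,i / k_d,i for every species with both constants defined."""
        out = {}
        for sp, kk in self.rate_constants.items():
            if "k_a" in kk and "k_d" in kk and kk["k_d"] > 0:
                out[sp] = kk["k_a"] / kk["k_d"]
        return out

    def with_overrides(self, **kw) -> "ModelParameters":
        """Return a copy with scalar fields and/or rate constants replaced.

        Rate constants are addressed as e.g. ``k_d_s=0.05`` or ``k_a_x=30``.
        """
        scalars = {}
        rc = {sp: dict(kk) for sp, kk in self.rate_constants.items()}
        for key, val in kw.items():
            if key.startswith(("k_a_", "k_d_")):
                kind, sp = key[:3], key[4:]
                if sp not in _SPECIES:
                    raise KeyError(f"unknown species in override {key!r}")
                rc.setdefault(sp, {})[kind] = float(val)
            elif key in ("k_ecm", "E_s", "I_n", "C_s", "p0", "v0", "D_r"):
                scalars[key] = float(val)
            else:
                raise KeyError(f"unknown parameter override {key!r}")
        return replace(self, rate_constants=rc, **scalars)

    def to_dict(self) -> dict:
        return {
            "k_ecm": self.k_ecm, "E_s": self.E_s, "I_n": self.I_n, "C_s": self.C_s,
            "p0": self.p0, "v0": self.v0, "D_r": self.D_r,
            "rate_constants": {sp: dict(kk) for sp, kk in self.rate_constants.items()},
        }


@dataclass(frozen=True)
class ScalingSpec:
    """Density-to-molecule-number conversion for stochastic simulation.

    ``n_star`` is the number-density scale shared by the adhesion-type species
    (N, S, X, P); myosin and Rac counts are amplified relative to their
    activators, M = K_m * n_star * m and R = K_r * n_star * r.
    """

    n_star: int = 3
    K_m: float = 10.0
    K_r: float = 10.0

    def __post_init__(self) -> None:
        if int(self.n_star) != self.n_star or self.n_star < 1:
            raise ValueError("n_star must be an integer >= 1")
        if self.K_m <= 0 or self.K_r <= 0:
            raise ValueError("K_m and K_r must be positive")

    @property
    def scales(self) -> dict[str, float]:
        ns = float(self.n_star)
        return {"n": ns, "s": ns, "m": self.K_m * ns, "x": ns, "r": self.K_r * ns, "p": ns}


def _from_dict(d: Mapping) -> ModelParameters:
    d = dict(d)
    rc = {sp: dict(kk) for sp, kk in d.pop("rate_constants", {}).items()}
    known = {"k_ecm", "E_s", "I_n", "C_s", "p0", "v0", "D_r"}
    unknown = set(d) - known
    if unknown:
        raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
    params = ModelParameters(rate_constants=rc, **{k: float(v) for k, v in d.items()})
    # consistency of stated K ratios is implied by construction; verify k_a/k_d finite
    for sp, K in params.K_ratios.items():
        ka, kd = params.k_a(sp), params.k_d(sp)
        if kd > 0 and abs(K - ka / kd) > _REL_TOL * max(1.0, abs(K)):
            raise ValueError(f"inconsistent K ratio for species {sp!r}")
    return params


def load_parameters(path: str | Path) -> ModelParameters:
    """Load a parameter file (YAML or JSON, keyed like ModelParameters)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _from_dict(data)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def base_case(**overrides) -> ModelParameters:
    """The canonical base-case parameter set shipped with the package."""
    ref = resources.files("adhesim.data").joinpath("base_case.yaml")
    params = _from_dict(yaml.safe_load(ref.read_text()))
    return params.with_overrides(**overrides) if overrides else params
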