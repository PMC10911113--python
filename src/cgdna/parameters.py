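"""Force-field parameter sets.

Three parameter containers cover the whole energy function:

* :class:`DnaParameterSet` - bonded terms, base stacking and hydrogen
  bonding 12-10 tables, WCA excluded volume, and the global scaling
  factors used during parameterisation of the melting curve.
* :class:`HpsParameterSet` - hydropathy-scale (HPS) short-range pair
  parameters for amino acids and DNA beads, used for protein-protein
  and protein-DNA interactions.
* :class:`ElectrostaticsContext` - Debye-Hueckel screened Coulomb
  settings.

All defaults are the published values of the model; any constant can be
overridden via :meth:`DnaParameterSet.with_overrides` or a YAML override
file (see :func:`load_overrides`).
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import yaml

from .units import KB, COULOMB  # noqa: F401  (re-exported for convenience)


def _pairkey(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# DNA model
# ---------------------------------------------------------------------------

#: bead masses, amu
DNA_MASSES = {"BB": 178.08, "A": 134.1, "T": 125.1, "C": 110.1, "G": 150.1}

#: base stacking 12-10 well depths delta_stack (kcal/mol); sigma_stack = 3.6 A
STACK_DELTA = {
    _pairkey("A", "A"): 9.7,
    _pairkey("A", "T"): 8.6,
    _pairkey("A", "C"): 7.8,
    _pairkey("A", "G"): 10.3,
    _pairkey("T", "T"): 7.7,
    _pairkey("T", "C"): 6.9,
    _pairkey("T", "G"): 9.2,
    _pairkey("C", "C"): 6.2,
    _pairkey("C", "G"): 8.3,
    _pairkey("G", "G"): 11.0,
}

#: 2-bead hydrogen bonding (sigma_HB A, delta_HB kcal/mol) per Watson-Crick pair
HB2 = {_pairkey("A", "T"): (6.0, 2.7), _pairkey("C", "G"): (5.5, 3.3)}

#: 3-bead dummy-site hydrogen bonding, lower-case species a/t/c/g
HB3 = {_pairkey("a", "t"): (1.65, 8.5), _pairkey("c", "g"): (1.65, 10.4)}


@dataclass
class DnaParameterSet:
    """All constants of the 2-/3-bead DNA energy function.

    The stacking/HB tables ship with the global melting-calibration
    factors (``delta_stack_scale`` = 2.1, ``delta_hb_scale`` = 0.95)
    already folded in, exactly as published; :meth:`scaled` rescales
    them *relative to those defaults* for parameter scans, so the
    factors are never applied twice.
    """

    # bonded
    k_bond: float = 50.0                       # kcal/(mol A^2), all DNA bonds
    r0: dict = field(default_factory=lambda: {
        "bb-bb": 5.5, "bb-base": 5.75, "base-hb": 1.95})
    k_angle: dict = field(default_factory=lambda: {"backbone": 40.0, "hb": 80.0})
    theta0: dict = field(default_factory=lambda: {"backbone": 180.0, "hb": 180.0})

    # stacking (12-10)
    sigma_stack: float = 3.6                   # A, all base pairs
    stack_delta: dict = field(default_factory=lambda: dict(STACK_DELTA))
    r_stack: float = 6.2                       # A cutoff

    # hydrogen bonding (12-10)
    hb2: dict = field(default_factory=lambda: dict(HB2))
    r_hb2: float = 9.5                         # A cutoff, 2-bead
    hb3: dict = field(default_factory=lambda: dict(HB3))
    r_hb3: float = 3.3                         # A cutoff, 3-bead (= 2 sigma_HB)

    # excluded volume (WCA)
    eps_ex: float = 4.0                        # kcal/mol
    sigma_ex: float = 5.5                      # A
    #: apply WCA also to backbone-involving DNA pairs (off = literal
    #: base-only rule of the model definition)
    wca_backbone: bool = False

    # documented global calibration factors (already folded into the tables)
    delta_stack_scale: float = 2.1
    delta_hb_scale: float = 0.95

    # ------------------------------------------------------------------
    def stack_params(self, base_i: str, base_j: str) -> tuple[float, float]:
        """(sigma, delta) for a stacking pair of base species."""
        return self.sigma_stack, self.stack_delta[_pairkey(base_i, base_j)]

    def hb_params(self, sp_i: str, sp_j: str) -> tuple[float, float, float]:
        """(sigma, delta, cutoff) for an HB pair (base or dummy species)."""
        key = _pairkey(sp_i, sp_j)
        if key in self.hb2:
            sig, dlt = self.hb2[key]
            return sig, dlt, self.r_hb2
        if key in self.hb3:
            sig, dlt = self.hb3[key]
            return sig, dlt, self.r_hb3
        raise KeyError(f"no hydrogen-bonding parameters for pair {key}")

    def scaled(self, delta_stack: float | None = None,
               delta_hb: float | None = None) -> "DnaParameterSet":
        """Return a copy with stacking/HB strengths rescaled.

        ``delta_stack``/``delta_hb`` are new *global* scale factors; the
        tables are multiplied by ``new/default`` so the published tables
        correspond exactly to the default factors.
        """
        out = copy.deepcopy(self)
        if delta_stack is not None:
            f = delta_stack / self.delta_stack_scale
            out.stack_delta = {k: v * f for k, v in self.stack_delta.items()}
            out.delta_stack_scale = delta_stack
        if delta_hb is not None:
            f = delta_hb / self.delta_hb_scale
            out.hb2 = {k: (s, d * f) for k, (s, d) in self.hb2.items()}
            out.hb3 = {k: (s, d * f) for k, (s, d) in self.hb3.items()}
            out.delta_hb_scale = delta_hb
        return out

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuple keys -> "X-Y" strings for YAML
        for name in ("stack_delta", "hb2", "hb3"):
            d[name] = {"-".join(k): v for k, v in d[name].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DnaParameterSet":
        d = copy.deepcopy(d)
        for name in ("stack_delta", "hb2", "hb3"):
            if name in d:
                d[name] = {tuple(k.split("-")): (tuple(v) if isinstance(v, list) else v)
                           for k, v in d[name].items()}
        return cls(**d)

    def with_overrides(self, overrides: dict) -> "DnaParameterSet":
        """Apply a (possibly nested) override mapping onto a copy."""
        d = self.to_dict()
        _deep_update(d, overrides)
        return self.from_dict(d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "DnaParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _deep_update(base: dict, upd: dict) -> None:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def load_overrides(path: str) -> dict:
    """Load a YAML parameter-override file."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


# ---------------------------------------------------------------------------
# HPS protein / protein-DNA model
# ---------------------------------------------------------------------------

#: amino-acid vdW diameters sigma (A), shared by the Urry and KR scales
AA_SIGMA = {
    "A": 5.04, "R": 6.56, "N": 5.68, "D": 5.58, "C": 5.48,
    "Q": 6.02, "E": 5.92, "G": 4.50, "H": 6.08, "I": 6.18,
    "L": 6.18, "K": 6.36, "M": 6.18, "F": 6.36, "P": 5.56,
    "S": 5.18, "T": 5.62, "W": 6.78, "Y": 6.46, "V": 5.86,
}

#: hydropathies on the Urry scale (HPS-Urry, Regy et al. 2021)
AA_LAMBDA_URRY = {
    "A": 0.602942, "R": 0.558824, "N": 0.588236, "D": 0.294118,
    "C": 0.64706,  "Q": 0.558824, "E": 0.0,      "G": 0.57353,
    "H": 0.764706, "I": 0.705882, "L": 0.720588, "K": 0.382353,
    "M": 0.676471, "F": 0.82353,  "P": 0.758824, "S": 0.588236,
    "T": 0.588236, "W": 1.0,      "Y": 0.897059, "V": 0.664706,
}

#: hydropathies on the Kapcha-Rossky scale (HPS-KR, Dignon et al. 2018)
AA_LAMBDA_KR = {
    "A": 0.730, "R": 0.000, "N": 0.432, "D": 0.378, "C": 0.595,
    "Q": 0.514, "E": 0.459, "G": 0.649, "H": 0.514, "I": 0.973,
    "L": 0.973, "K": 0.514, "M": 0.838, "F": 1.000, "P": 1.000,
    "S": 0.595, "T": 0.676, "W": 0.946, "Y": 0.865, "V": 0.892,
}

AA_CHARGE = {aa: 0.0 for aa in AA_SIGMA}
AA_CHARGE.update({"R": 1.0, "K": 1.0, "D": -1.0, "E": -1.0})

#: average amino-acid masses, amu
AA_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}

#: hydropathies of the DNA beads in the HPS framework (CHARMM27-derived)
DNA_LAMBDA = {"BB": 0.38, "A": 0.40, "T": 0.54, "C": 0.59, "G": 0.35}


@dataclass
class HpsParameterSet:
    """Hydropathy-scale short-range pair parameters.

    Per-species lambda (dimensionless), sigma (A) and charge (e), with a
    global interaction strength ``eps`` = 0.2 kcal/mol and arithmetic
    mixing for both lambda and sigma.  Dummy HB beads of the 3-bead DNA
    model carry no HPS interaction (eps = 0 with everything).
    """

    scale: str = "urry"
    eps: float = 0.2
    cutoff: float = 25.0          # A, plain truncation
    aa_lambda: dict = field(default_factory=lambda: dict(AA_LAMBDA_URRY))
    aa_sigma: dict = field(default_factory=lambda: dict(AA_SIGMA))
    dna_lambda: dict = field(default_factory=lambda: dict(DNA_LAMBDA))
    dna_sigma: float = 5.5        # backbone and base beads

    @classmethod
    def urry(cls, **kw) -> "HpsParameterSet":
        return cls(scale="urry", aa_lambda=dict(AA_LAMBDA_URRY), **kw)

    @classmethod
    def kr(cls, **kw) -> "HpsParameterSet":
        return cls(scale="kr", aa_lambda=dict(AA_LAMBDA_KR), **kw)

    @classmethod
    def by_name(cls, name: str, **kw) -> "HpsParameterSet":
        try:
            return {"urry": cls.urry, "kr": cls.kr}[name.lower()](**kw)
        except KeyError:
            raise KeyError(f"unknown HPS scale {name!r} (use 'urry' or 'kr')")

    def zero_lambda(self) -> "HpsParameterSet":
        """All hydropathies set to zero: purely repulsive short range."""
        out = copy.deepcopy(self)
        out.aa_lambda = {k: 0.0 for k in out.aa_lambda}
        out.dna_lambda = {k: 0.0 for k in out.dna_lambda}
        out.scale = self.scale + "(lambda=0)"
        return out

    def species_params(self, kind: str, species: str) -> tuple[float, float]:
        """(lambda, sigma) for a bead of the given kind/species.

        ``kind`` is one of ``aa``, ``backbone``, ``base``, ``hb``.
        Raises ``KeyError`` for species without an entry.
        """
        if kind == "aa":
            return self.aa_lambda[species], self.aa_sigma[species]
        if kind == "backbone":
            return self.dna_lambda["BB"], self.dna_sigma
        if kind == "base":
            return self.dna_lambda[species], self.dna_sigma
        if kind == "hb":
            # dummy beads: eps = 0 with everything; lambda/sigma unused
            return 0.0, 1.65
        raise KeyError(f"unknown bead kind {kind!r}")

    def pair_params(self, kind_i: str, sp_i: str,
                    kind_j: str, sp_j: str) -> tuple[float, float, float]:
        """Mixed (sigma, lambda, eps) for a pair of species."""
        li, si = self.species_params(kind_i, sp_i)
        lj, sj = self.species_params(kind_j, sp_j)
        eps = 0.0 if (kind_i == "hb" or kind_j == "hb") else self.eps
        return 0.5 * (si + sj), 0.5 * (li + lj), eps


# ---------------------------------------------------------------------------
# Electrostatics
# ---------------------------------------------------------------------------

#: published Debye lengths (A) at the two salt conditions used by the model
SALT_KAPPA = {100.0: 10.0, 120.0: 8.8}


@dataclass(frozen=True)
class ElectrostaticsContext:
    """Debye-Hueckel screened Coulomb settings.

    ``kappa`` is the Debye screening length in A; the interaction is
    truncated at ``3.5 * kappa``.
    """

    kappa: float = 10.0
    eps_r: float = 80.0

    @property
    def cutoff(self) -> float:
        return 3.5 * self.kappa

    @property
    def prefactor(self) -> float:
        """k_e / eps_r, kcal A/(mol e^2)."""
        return COULOMB / self.eps_r

    @classmethod
    def from_salt(cls, salt_mm: float, eps_r: float = 80.0) -> "ElectrostaticsContext":
        """Context for a monovalent salt concentration in mM.

        The two published conditions map to their printed Debye lengths
        (100 mM -> 10 A, 120 mM -> 8.8 A); any other concentration uses
        the room-temperature Debye formula kappa = 3.04/sqrt(I[M]) A.
        """
        if salt_mm in SALT_KAPPA:
            return cls(kappa=SALT_KAPPA[salt_mm], eps_r=eps_r)
        if salt_mm <= 0:
            raise ValueError("salt concentration must be positive")
        return cls(kappa=3.04 / (salt_mm / 1000.0) ** 0.5, eps_r=eps_r)
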