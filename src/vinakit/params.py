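"""Scoring-function parameter sets: weights, term parameters, radii.

A :class:`TermParameterSet` fully determines one Vina-family scoring
function.  The two built-in presets (``vina``, ``vinardo``) ship as flat
key-value data files and are loaded verbatim; custom functions are the
same file format with different numbers (optionally including a generic
m-n Lennard-Jones steric term).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

__all__ = ["TermParameterSet", "load_params", "dump_params", "vina_params", "vinardo_params"]

_METAL_ELEMENTS = {"Zn", "Mn", "Mg", "Ca", "Fe", "Ni", "Cu", "Co", "K", "Na", "Cd"}


@dataclass(frozen=True)
class TermParameterSet:
    """Complete parameterization of one scoring function.

    Weights w1..w5 multiply Gauss1, Gauss2, Repulsion, Hydrophobic and
    HBond; o/s are Gaussian offsets/widths, p1/p2 the hydrophobic
    onset/offset and h1 the H-bond onset (all in angstrom, measured on the
    surface distance d = r - Ri - Rj).  ``radii`` maps AutoDock type (or
    element) to the scoring radius.  ``torsion_coeff`` scales the
    rotatable-bond entropy penalty; ``cutoff`` truncates pair sums at
    surface distance d >= cutoff.
    """

    name: str = "custom"
    w1: float = 0.0  # gauss1
    w2: float = 0.0  # gauss2
    w3: float = 0.0  # repulsion
    w4: float = 0.0  # hydrophobic
    w5: float = 0.0  # hbond
    o1: float = 0.0
    s1: float = 0.5
    gauss2_enabled: bool = False
    o2: float = 3.0
    s2: float = 2.0
    p1: float = 0.5
    p2: float = 1.5
    h1: float = -0.7
    cutoff: float = 8.0
    torsion_coeff: float = 0.05846
    radii: dict = field(default_factory=dict)
    fluorine_hydrophobic: bool = True
    # optional generic m-n Lennard-Jones steric term (custom functions only)
    lj_weight: float = 0.0
    lj_m: int = 4
    lj_n: int = 8

    def __post_init__(self):
        if self.s1 <= 0:
            raise ValueError("Gauss1 width s1 must be positive")
        if self.gauss2_enabled and self.s2 <= 0:
            raise ValueError("Gauss2 width s2 must be positive")
        if not self.p1 < self.p2:
            raise ValueError("hydrophobic onset p1 must be below offset p2")
        if not self.h1 < 0:
            raise ValueError("H-bond onset h1 must be negative")
        if self.lj_weight != 0.0 and not (0 < self.lj_m < self.lj_n):
            raise ValueError("Lennard-Jones exponents require n > m > 0")

    def radius_of(self, ad_type: str, element: str) -> float:
        """Scoring radius for an atom, by AutoDock type then element."""
        r = self.radii.get(ad_type)
        if r is None:
            r = self.radii.get(element)
        if r is None and element in _METAL_ELEMENTS:
            r = self.radii.get("metal")
        if r is None:
            raise KeyError(f"no radius for atom type {ad_type!r} (element {element})")
        return r

    def with_overrides(self, **kwargs) -> "TermParameterSet":
        """Copy with scalar-parameter or ``radius_<TYPE>`` overrides."""
        radii = dict(self.radii)
        plain = {}
        for key, val in kwargs.items():
            if key.startswith("radius_"):
                radii[key[len("radius_"):]] = val
            else:
                plain[key] = val
        return replace(self, radii=radii, name=plain.pop("name", "custom"), **plain)


_WEIGHT_KEYS = {
    "gauss1": "w1",
    "gauss2": "w2",
    "repulsion": "w3",
    "hydrophobic": "w4",
    "hbond": "w5",
    "lj": "lj_weight",
}
_SCALAR_KEYS = {
    "gauss1_offset": ("o1", float),
    "gauss1_width": ("s1", float),
    "gauss2_offset": ("o2", float),
    "gauss2_width": ("s2", float),
    "hydrophobic_onset": ("p1", float),
    "hydrophobic_offset": ("p2", float),
    "hbond_onset": ("h1", float),
    "cutoff": ("cutoff", float),
    "torsion_coeff": ("torsion_coeff", float),
    "lj_m": ("lj_m", int),
    "lj_n": ("lj_n", int),
}
_BOOL_KEYS = {"gauss2_enabled", "fluorine_hydrophobic"}


def load_params(path_or_text: str) -> TermParameterSet:
    """Load a parameter set from the flat key-value format.

    Lines are ``key value`` or ``weight <term> value`` / ``radius <type>
    value``; ``#`` starts a comment.
    """
    text = path_or_text
    if "\n" not in path_or_text:
        with open(path_or_text) as fh:
            text = fh.read()
    kwargs: dict = {"radii": {}}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        key = parts[0]
        if key == "name":
            kwargs["name"] = parts[1]
        elif key == "weight":
            if parts[1] not in _WEIGHT_KEYS:
                raise ValueError(f"unknown term in weight line: {parts[1]!r}")
            kwargs[_WEIGHT_KEYS[parts[1]]] = float(parts[2])
        elif key == "radius":
            kwargs["radii"][parts[1]] = float(parts[2])
        elif key in _SCALAR_KEYS:
            attr, conv = _SCALAR_KEYS[key]
            kwargs[attr] = conv(parts[1])
        elif key in _BOOL_KEYS:
            kwargs[key] = parts[1].lower() in ("true", "1", "yes")
        else:
            raise ValueError(f"unknown parameter key: {key!r}")
    return TermParameterSet(**kwargs)


def dump_params(params: TermParameterSet) -> str:
    """Serialize a parameter set back to the flat file format."""
    lines = [f"name {params.name}"]
    for term, attr in _WEIGHT_KEYS.items():
        val = getattr(params, attr)
        if term == "lj" and val == 0.0:
            continue
        lines.append(f"weight {term} {val}")
    lines += [
        f"gauss1_offset {params.o1}",
        f"gauss1_width {params.s1}",
        f"gauss2_enabled {str(params.gauss2_enabled).lower()}",
    ]
    if params.gauss2_enabled:
        lines += [f"gauss2_offset {params.o2}", f"gauss2_width {params.s2}"]
    lines += [
        f"hydrophobic_onset {params.p1}",
        f"hydrophobic_offset {params.p2}",
        f"hbond_onset {params.h1}",
        f"cutoff {params.cutoff}",
        f"torsion_coeff {params.torsion_coeff}",
        f"fluorine_hydrophobic {str(params.fluorine_hydrophobic).lower()}",
    ]
    if params.lj_weight != 0.0:
        lines += [f"lj_m {params.lj_m}", f"lj_n {params.lj_n}"]
    for typ, r in params.radii.items():
        lines.append(f"radius {typ} {r}")
    return "\n".join(lines) + "\n"


def _load_preset(name: str) -> TermParameterSet:
    text = resources.files("vinakit.data").joinpath(f"{name}.params").read_text()
    return load_params(text)


def vina_params() -> TermParameterSet:
    """The Vina parameter set (original weights, parameters, radii)."""
    return _load_preset("vina")


def vinardo_params() -> TermParameterSet:
    """The Vinardo parameter set (single Gaussian, retuned radii)."""
    return _load_preset("vinardo")


def get_params(name_or_path: str) -> TermParameterSet:
    """Resolve ``vina``/``vinardo`` or load a custom parameter file."""
    if name_or_path == "vina":
        return vina_params()
    if name_or_path == "vinardo":
        return vinardo_params()
    return load_params(name_or_path)
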