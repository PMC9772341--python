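"""Sequence featurization for thermophilicity prediction.

Three feature blocks make up the default 50-component representation of a
protein sequence:

* 20 amino-acid compositions (fraction of each canonical residue among the
  unambiguous residues);
* g-gap dipeptide compositions ``a(x)_g b`` — residue ``a``, then ``g``
  arbitrary residues, then residue ``b`` — for a selected subset of the
  1200 candidates over g in {0, 1, 2} (10 retained by default);
* 20 residue-type / physicochemical features (class compositions and ratios,
  mean maximum solvent-accessible area, molecular weight, heat capacity,
  isoelectric-point-adjacent charge ratios, IVYWREL composition).

Ambiguity codes (B/Z/X/U/O) are excluded from all composition denominators.
Molecular weight and isoelectric point utilities live here too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, DegenerateInputError
from .io import CANONICAL_AA, SequenceRecord

GgapDescriptor = tuple  # (a: str, g: int, b: str)


def _load_data(name: str) -> dict:
    with resources.files("petmine.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class ResidueClassTable:
    """Named residue sets driving the class-composition features."""

    classes: dict

    @classmethod
    def default(cls) -> "ResidueClassTable":
        raw = _load_data("residue_classes.json")["feature_classes"]
        table = cls({k: frozenset(v) for k, v in raw.items()})
        table.validate()
        return table

    def validate(self):
        c = self.classes
        fixed = {
            "efmr": set("EFMR"),
            "tiny": set("AGPS"),
            "small": set("TD"),
            "ivywrel": set("IVYWREL"),
            "positive": set("RK"),
            "negative": set("DE"),
        }
        for name, members in fixed.items():
            if set(c[name]) != members:
                raise ConfigError(f"residue class {name!r} must be {sorted(members)}")
        if set(c["cyclic"]) | set(c["acyclic"]) != set(CANONICAL_AA) or (
            set(c["cyclic"]) & set(c["acyclic"])
        ):
            raise ConfigError("cyclic and acyclic must partition the 20 residues")
        for name, members in c.items():
            if not members:
                raise ConfigError(f"residue class {name!r} is empty")
            if not set(members) <= set(CANONICAL_AA):
                raise ConfigError(f"residue class {name!r} has non-canonical members")

    def __getitem__(self, name: str) -> frozenset:
        return self.classes[name]


@dataclass(frozen=True)
class ConstantsTable:
    """Per-residue physical constants (max ASA, heat capacity, mass, pKa set)."""

    max_asa: dict
    heat_capacity: dict
    mass: dict
    water_mass: float
    pka: dict
    background: dict

    @classmethod
    def default(cls) -> "ConstantsTable":
        raw = _load_data("residue_constants.json")
        table = cls(
            max_asa=raw["max_asa"],
            heat_capacity=raw["heat_capacity"],
            mass=raw["mass"],
            water_mass=raw["water_mass"],
            pka=raw["pka"],
            background=raw["background"],
        )
        for tab in (table.max_asa, table.heat_capacity, table.mass):
            missing = set(CANONICAL_AA) - set(tab)
            if missing:
                raise ConfigError(f"constants table missing residues {sorted(missing)}")
            if any(not (v > 0 and np.isfinite(v)) for v in tab.values()):
                raise ConfigError("constants must be finite and positive")
        return table


_DEFAULT_CLASSES = ResidueClassTable.default()
_DEFAULT_CONSTANTS = ConstantsTable.default()

#: Fallback g-gap selection used when no trained selection is supplied.
#: Charged/aliphatic pairings across the three gap lengths; replace with the
#: output of thermoprot.select_ggap_features for any trained model.
DEFAULT_GGAP_DESCRIPTORS: list[GgapDescriptor] = [
    ("E", 0, "E"), ("E", 0, "K"), ("K", 0, "E"), ("I", 0, "I"), ("V", 0, "V"),
    ("E", 1, "E"), ("K", 1, "K"), ("I", 1, "V"), ("E", 2, "E"), ("L", 2, "L"),
]

PHYS_FEATURE_NAMES = [
    "comp_acidic", "comp_basic", "comp_non_polar", "comp_acyclic",
    "comp_aliphatic", "comp_aromatic", "comp_charged", "comp_efmr",
    "ratio_basic_acidic", "ratio_non_polar_polar", "ratio_acyclic_cyclic",
    "ratio_charged_non_charged", "comp_tiny", "comp_small", "mean_max_asa",
    "ratio_ek_qh", "ratio_charged_polar", "comp_ivywrel", "mol_weight",
    "heat_capacity",
]


def _seq_of(seq) -> str:
    return seq.residues if isinstance(seq, SequenceRecord) else str(seq).upper()


def aa_composition(seq) -> dict:
    """Fraction of each canonical residue among unambiguous residues (sums to 1)."""
    s = _seq_of(seq)
    counts = {a: 0 for a in CANONICAL_AA}
    n = 0
    for c in s:
        if c in counts:
            counts[c] += 1
            n += 1
    if n == 0:
        raise DegenerateInputError("sequence has no unambiguous residues")
    return {a: counts[a] / n for a in CANONICAL_AA}


def enumerate_ggap_candidates(g_values: Iterable[int] = (0, 1, 2)) -> list[GgapDescriptor]:
    """All (a, g, b) descriptors in deterministic lexicographic (g, a, b) order."""
    gs = sorted(set(g_values))
    if not gs:
        raise ConfigError("g_values must be nonempty")
    if any(g < 0 for g in gs):
        raise ConfigError("gap lengths must be >= 0")
    return [(a, g, b) for g in gs for a in CANONICAL_AA for b in CANONICAL_AA]


def ggap_composition(seq, descriptor: GgapDescriptor) -> float:
    """Occurrence fraction of a(x)_g b among the L-g-1 windows of the sequence.

    Windows whose a or b slot holds an ambiguity code never count as matches;
    the gap slots may hold any letter.  Sequences too short for a single
    window return 0.0 (short-sequence convention, keeping fixed-length
    feature vectors computable).
    """
    a, g, b = descriptor
    if g < 0:
        raise ConfigError("gap length must be >= 0")
    s = _seq_of(seq)
    n_windows = len(s) - g - 1
    if n_windows <= 0:
        return 0.0
    hits = sum(1 for i in range(n_windows) if s[i] == a and s[i + g + 1] == b)
    return hits / n_windows


def _comp(s: str, members: frozenset, n: int) -> float:
    return sum(1 for c in s if c in members) / n


def _count(s: str, members) -> int:
    members = set(members)
    return sum(1 for c in s if c in members)


def physicochemical_features(
    seq,
    classes: ResidueClassTable = _DEFAULT_CLASSES,
    constants: ConstantsTable = _DEFAULT_CONSTANTS,
) -> dict:
    """The 20 residue-type/physicochemical features.

    Compositions are class counts over the unambiguous length; ratios are
    smoothed as (num + 1)/(den + 1) so short or extreme sequences stay
    finite.  Mean max-ASA and heat capacity are length-normalized sums of
    per-residue constants; molecular weight is the residue-mass sum plus one
    water.
    """
    raw = _seq_of(seq)
    s = "".join(c for c in raw if c in CANONICAL_AA)
    n = len(s)
    if n == 0:
        raise DegenerateInputError("sequence has no unambiguous residues")
    cl = classes
    charged = _count(s, cl["charged"])
    polar = _count(s, cl["polar"])
    out = {
        "comp_acidic": _comp(s, cl["acidic"], n),
        "comp_basic": _comp(s, cl["basic"], n),
        "comp_non_polar": _comp(s, cl["non_polar"], n),
        "comp_acyclic": _comp(s, cl["acyclic"], n),
        "comp_aliphatic": _comp(s, cl["aliphatic"], n),
        "comp_aromatic": _comp(s, cl["aromatic"], n),
        "comp_charged": _comp(s, cl["charged"], n),
        "comp_efmr": _comp(s, cl["efmr"], n),
        "ratio_basic_acidic": (_count(s, cl["basic"]) + 1) / (_count(s, cl["acidic"]) + 1),
        "ratio_non_polar_polar": (_count(s, cl["non_polar"]) + 1) / (polar + 1),
        "ratio_acyclic_cyclic": (_count(s, cl["acyclic"]) + 1) / (_count(s, cl["cyclic"]) + 1),
        "ratio_charged_non_charged": (charged + 1) / (n - charged + 1),
        "comp_tiny": _comp(s, cl["tiny"], n),
        "comp_small": _comp(s, cl["small"], n),
        "mean_max_asa": sum(constants.max_asa[c] for c in s) / n,
        "ratio_ek_qh": (_count(s, "EK") + 1) / (_count(s, "QH") + 1),
        "ratio_charged_polar": (charged + 1) / (polar + 1),
        "comp_ivywrel": _comp(s, cl["ivywrel"], n),
        "mol_weight": molecular_weight(raw, constants),
        "heat_capacity": sum(constants.heat_capacity[c] for c in s) / n,
    }
    return out


def molecular_weight(seq, constants: ConstantsTable = _DEFAULT_CONSTANTS) -> float:
    """Average molecular weight in Da (residue masses + one water).

    Ambiguity codes contribute the mean canonical residue mass.
    """
    s = _seq_of(seq)
    mean_mass = sum(constants.mass.values()) / len(constants.mass)
    total = constants.water_mass
    for c in s:
        total += constants.mass.get(c, mean_mass)
    return total


def net_charge(seq, pH: float, pka: dict | None = None) -> float:
    """Henderson-Hasselbalch net charge at a given pH (termini included)."""
    pka = pka or _DEFAULT_CONSTANTS.pka
    s = _seq_of(seq)
    positive = [("n_terminus", 1), ("K", s.count("K")), ("R", s.count("R")),
                ("H", s.count("H"))]
    negative = [("c_terminus", 1), ("D", s.count("D")), ("E", s.count("E")),
                ("C", s.count("C")), ("Y", s.count("Y"))]
    q = 0.0
    for key, count in positive:
        q += count / (1.0 + 10.0 ** (pH - pka[key]))
    for key, count in negative:
        q -= count / (1.0 + 10.0 ** (pka[key] - pH))
    return q


def isoelectric_point(seq, pka: dict | None = None, tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    The net charge is strictly decreasing in pH so the root is unique.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


class FeatureVector(dict):
    """Ordered named feature values; iteration follows insertion order."""

    @property
    def names(self) -> list[str]:
        return list(self.keys())

    def to_array(self) -> np.ndarray:
        return np.array(list(self.values()), dtype=float)


def feature_names(selected_ggap: Sequence[GgapDescriptor] | None = None) -> list[str]:
    sel = DEFAULT_GGAP_DESCRIPTORS if selected_ggap is None else list(selected_ggap)
    return (
        [f"aac_{a}" for a in CANONICAL_AA]
        + [f"ggap_{a}|{g}|{b}" for a, g, b in sel]
        + [f"phys_{name}" for name in PHYS_FEATURE_NAMES]
    )


def featurize(
    seq,
    selected_ggap: Sequence[GgapDescriptor] | None = None,
    classes: ResidueClassTable = _DEFAULT_CLASSES,
    constants: ConstantsTable = _DEFAULT_CONSTANTS,
) -> FeatureVector:
    """Full feature vector: 20 aac + selected g-gap + 20 physicochemical."""
    sel = DEFAULT_GGAP_DESCRIPTORS if selected_ggap is None else list(selected_ggap)
    vec = FeatureVector()
    aac = aa_composition(seq)
    for a in CANONICAL_AA:
        vec[f"aac_{a}"] = aac[a]
    for a, g, b in sel:
        vec[f"ggap_{a}|{g}|{b}"] = ggap_composition(seq, (a, g, b))
    phys = physicochemical_features(seq, classes, constants)
    for name in PHYS_FEATURE_NAMES:
        vec[f"phys_{name}"] = phys[name]
    return vec


def featurize_matrix(
    records: Sequence,
    selected_ggap: Sequence[GgapDescriptor] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Stack feature vectors for many records into an (n, p) array."""
    vectors = [featurize(r, selected_ggap) for r in records]
    names = feature_names(selected_ggap)
    return np.array([v.to_array() for v in vectors]), names


_AA_INDEX = {a: i for i, a in enumerate(CANONICAL_AA)}


def ggap_matrix(records: Sequence, descriptors: Sequence[GgapDescriptor]) -> np.ndarray:
    """g-gap compositions only, one column per descriptor (selection stage input).

    Vectorized pair counting per gap length; agrees with
    :func:`ggap_composition` descriptor by descriptor.
    """
    descriptors = list(descriptors)
    by_g: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for g in sorted({g for _, g, _ in descriptors}):
        cols = np.array([j for j, (_, gg, _) in enumerate(descriptors) if gg == g])
        pairs = np.array(
            [_AA_INDEX[a] * 20 + _AA_INDEX[b] for a, gg, b in descriptors if gg == g]
        )
        by_g[g] = (cols, pairs)
    out = np.zeros((len(records), len(descriptors)))
    for i, rec in enumerate(records):
        s = _seq_of(rec)
        codes = np.array([_AA_INDEX.get(c, -1) for c in s], dtype=np.int64)
        L = len(codes)
        for g, (cols, pairs) in by_g.items():
            n_windows = L - g - 1
            if n_windows <= 0:
                continue
            first = codes[:n_windows]
            second = codes[g + 1:]
            ok = (first >= 0) & (second >= 0)
            counts = np.bincount(first[ok] * 20 + second[ok], minlength=400)
            out[i, cols] = counts[pairs] / n_windows
    return out
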