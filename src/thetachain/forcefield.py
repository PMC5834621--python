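"""Force-field parameter loading, validation and unit normalisation.

Two on-disk dialects are supported:

``native-config``
    A YAML document with an explicit ``energy_unit`` (``kJ/mol`` or
    ``kcal/mol``) and ``length_unit`` (``nm`` or ``angstrom``).  This is the
    canonical, round-trippable format; the packaged parameter sets use it.

``charmm-prm-rtf``
    A subset of the CHARMM parameter/topology text format: ``BONDS``,
    ``ANGLES`` (with optional Urey--Bradley columns), ``DIHEDRALS``,
    ``IMPROPER`` and ``NONBONDED`` (with optional 1--4 columns) sections,
    plus RTF-style ``ATOM name type charge`` lines for partial charges.
    Energies are kcal/mol and lengths Angstrom, converted on load.

All energies are stored in kJ/mol, lengths in nm, angles/phases in degrees.
Bond, angle and dihedral keys resolve irrespective of tuple direction, and
dihedral/improper lookups honour CHARMM wildcard (``X``) precedence:
exact match > single wildcard > double wildcard.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .constants import ANGSTROM_TO_NM, KCAL_TO_KJ

WILDCARD = "X"


class ForceFieldError(ValueError):
    """Malformed, ambiguous or missing force-field data."""


class MissingParameterError(ForceFieldError):
    """A required parameter record does not exist."""


@dataclass(frozen=True)
class BondType:
    k: float          # kJ/mol/nm^2
    b0: float         # nm


@dataclass(frozen=True)
class AngleType:
    k: float          # kJ/mol/rad^2
    theta0: float     # degrees
    k_ub: float = 0.0     # kJ/mol/nm^2 (Urey-Bradley)
    s0: float = 0.0       # nm (Urey-Bradley 1-3 distance)


@dataclass(frozen=True)
class DihedralTerm:
    K: float          # kJ/mol
    n: int            # multiplicity >= 1
    phase: float      # degrees in [0, 360)


@dataclass(frozen=True)
class LJType:
    eps: float            # kJ/mol (well depth, >= 0)
    rmin_half: float      # nm
    eps_14: float | None = None
    rmin_half_14: float | None = None

    def pair_14(self) -> tuple[float, float]:
        """Effective (eps, rmin_half) used for 1-4 pairs."""
        if self.eps_14 is None or self.rmin_half_14 is None:
            return self.eps, self.rmin_half
        return self.eps_14, self.rmin_half_14


def _canon_pair(key: tuple[str, str]) -> tuple[str, str]:
    return min(key, tuple(reversed(key)))


def _canon_quad(key: tuple[str, ...]) -> tuple[str, ...]:
    return min(tuple(key), tuple(reversed(key)))


def _canon_triple(key: tuple[str, str, str]) -> tuple[str, str, str]:
    return min(tuple(key), tuple(reversed(key)))


@dataclass
class ForceFieldParameters:
    """All bonded/non-bonded constants in canonical internal units."""

    bond_types: dict[tuple[str, str], BondType] = field(default_factory=dict)
    angle_types: dict[tuple[str, str, str], AngleType] = field(default_factory=dict)
    dihedral_terms: dict[tuple[str, ...], tuple[DihedralTerm, ...]] = field(default_factory=dict)
    improper_terms: dict[tuple[str, ...], tuple[DihedralTerm, ...]] = field(default_factory=dict)
    lj_types: dict[str, LJType] = field(default_factory=dict)
    charges: dict[str, float] = field(default_factory=dict)
    elec14_scale: float = 0.83
    energy_unit: str = "kJ/mol"
    #: role -> (carbon/hydrogen atom type, charge class); roles are
    #: methyl_C, methylene_C, olefinic_C, methyl_H, methylene_H, olefinic_H.
    chain_atom_types: dict[str, str] = field(default_factory=dict)
    source: str = ""

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not (0.0 < self.elec14_scale <= 1.0):
            raise ForceFieldError(f"elec14_scale must be in (0, 1], got {self.elec14_scale}")
        for key, b in self.bond_types.items():
            if b.b0 <= 0:
                raise ForceFieldError(f"bond {key}: b0 must be positive")
        for key, terms in list(self.dihedral_terms.items()) + list(self.improper_terms.items()):
            for t in terms:
                if t.n < 1 or int(t.n) != t.n:
                    raise ForceFieldError(f"dihedral {key}: multiplicity {t.n} must be integer >= 1")
                if not (0.0 <= t.phase < 360.0):
                    raise ForceFieldError(f"dihedral {key}: phase {t.phase} outside [0, 360)")
        for name, lj in self.lj_types.items():
            if lj.eps < 0 or lj.rmin_half <= 0:
                raise ForceFieldError(f"LJ {name}: eps must be >= 0 and rmin_half > 0")
            if (lj.eps_14 is not None) and (lj.eps_14 < 0 or (lj.rmin_half_14 or 0) <= 0):
                raise ForceFieldError(f"LJ {name}: bad 1-4 record")

    # -- lookups ---------------------------------------------------------
    def bond(self, a: str, b: str) -> BondType:
        try:
            return self.bond_types[_canon_pair((a, b))]
        except KeyError:
            raise MissingParameterError(f"no bond type for ({a}, {b})") from None

    def angle(self, a: str, b: str, c: str) -> AngleType:
        try:
            return self.angle_types[_canon_triple((a, b, c))]
        except KeyError:
            raise MissingParameterError(f"no angle type for ({a}, {b}, {c})") from None

    def _quad_lookup(self, table, key, kindname):
        a, b, c, d = key
        tiers = (
            [(a, b, c, d)],
            [(WILDCARD, b, c, d), (a, b, c, WILDCARD)],
            [(WILDCARD, b, c, WILDCARD)],
        )
        for tier in tiers:
            hits = []
            for cand in tier:
                rec = table.get(_canon_quad(cand))
                if rec is not None:
                    hits.append((_canon_quad(cand), rec))
            # identical canonical keys can be produced twice within a tier
            uniq = dict(hits)
            if len(uniq) > 1:
                raise ForceFieldError(
                    f"ambiguous {kindname} match for {key}: {sorted(uniq)}")
            if uniq:
                return next(iter(uniq.values()))
        raise MissingParameterError(f"no {kindname} type for {key}")

    def dihedral(self, a: str, b: str, c: str, d: str) -> tuple[DihedralTerm, ...]:
        return self._quad_lookup(self.dihedral_terms, (a, b, c, d), "dihedral")

    def improper(self, a: str, b: str, c: str, d: str) -> tuple[DihedralTerm, ...]:
        return self._quad_lookup(self.improper_terms, (a, b, c, d), "improper")

    def lj(self, name: str) -> LJType:
        try:
            return self.lj_types[name]
        except KeyError:
            raise MissingParameterError(f"no LJ type for {name}") from None

    def charge(self, cls: str) -> float:
        try:
            return self.charges[cls]
        except KeyError:
            raise MissingParameterError(f"no charge for class {cls}") from None

    def content_hash(self) -> str:
        """Stable hash of every numerical constant (grid/partition cache key)."""
        import hashlib
        import json

        def enc(o):
            if isinstance(o, dict):
                return sorted((str(k), enc(v)) for k, v in o.items())
            if isinstance(o, (tuple, list)):
                return [enc(v) for v in o]
            if hasattr(o, "__dataclass_fields__"):
                return sorted((k, enc(getattr(o, k))) for k in o.__dataclass_fields__)
            return o
        payload = json.dumps(enc({
            "bond": self.bond_types, "angle": self.angle_types,
            "dih": self.dihedral_terms, "impr": self.improper_terms,
            "lj": self.lj_types, "q": self.charges,
            "e14": self.elec14_scale, "types": self.chain_atom_types,
        }), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def lookup_term(params: ForceFieldParameters, kind: str, key):
    """Uniform lookup front-end (kind in bond/angle/dihedral/improper/lj/charge)."""
    if kind == "bond":
        return params.bond(*key)
    if kind == "angle":
        return params.angle(*key)
    if kind == "dihedral":
        return params.dihedral(*key)
    if kind == "improper":
        return params.improper(*key)
    if kind == "lj":
        return params.lj(key if isinstance(key, str) else key[0])
    if kind == "charge":
        return params.charge(key if isinstance(key, str) else key[0])
    raise ForceFieldError(f"unknown parameter kind {kind!r}")


# ---------------------------------------------------------------------------
# native-config dialect
# ---------------------------------------------------------------------------

def _unit_factors(doc: dict, path: str) -> tuple[float, float]:
    eu = doc.get("energy_unit")
    if eu not in ("kJ/mol", "kcal/mol"):
        raise ForceFieldError(f"{path}: energy_unit must be 'kJ/mol' or 'kcal/mol', got {eu!r}")
    lu = doc.get("length_unit", "nm")
    if lu not in ("nm", "angstrom"):
        raise ForceFieldError(f"{path}: length_unit must be 'nm' or 'angstrom', got {lu!r}")
    fe = 1.0 if eu == "kJ/mol" else KCAL_TO_KJ
    fl = 1.0 if lu == "nm" else ANGSTROM_TO_NM
    return fe, fl


def _load_native(path: Path) -> ForceFieldParameters:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ForceFieldError(f"{path}: not a mapping document")
    fe, fl = _unit_factors(doc, str(path))
    ff = ForceFieldParameters(energy_unit="kJ/mol", source=str(path))
    ff.elec14_scale = float(doc.get("elec14_scale", 0.83))

    def put(table, key, rec, what):
        if key in table and table[key] != rec:
            raise ForceFieldError(f"{path}: duplicate conflicting {what} entry {key}")
        table[key] = rec

    for row in doc.get("bonds", []):
        key = _canon_pair(tuple(row["types"]))
        put(ff.bond_types, key,
            BondType(k=float(row["k"]) * fe / fl**2, b0=float(row["b0"]) * fl), "bond")
    for row in doc.get("angles", []):
        key = _canon_triple(tuple(row["types"]))
        put(ff.angle_types, key, AngleType(
            k=float(row["k"]) * fe, theta0=float(row["theta0"]),
            k_ub=float(row.get("k_ub", 0.0)) * fe / fl**2,
            s0=float(row.get("s0", 0.0)) * fl), "angle")
    for table, section in ((ff.dihedral_terms, "dihedrals"), (ff.improper_terms, "impropers")):
        for row in doc.get(section, []):
            key = _canon_quad(tuple(row["types"]))
            terms = tuple(DihedralTerm(K=float(t["K"]) * fe, n=int(t["n"]),
                                       phase=float(t["phase"]) % 360.0)
                          for t in row["terms"])
            put(table, key, terms, section[:-1])
    for row in doc.get("lj", []):
        name = row["type"]
        rec = LJType(
            eps=float(row["eps"]) * fe, rmin_half=float(row["rmin_half"]) * fl,
            eps_14=None if row.get("eps_14") is None else float(row["eps_14"]) * fe,
            rmin_half_14=None if row.get("rmin_half_14") is None
            else float(row["rmin_half_14"]) * fl)
        if name in ff.lj_types and ff.lj_types[name] != rec:
            raise ForceFieldError(f"{path}: duplicate conflicting LJ entry {name}")
        ff.lj_types[name] = rec
    for cls, q in (doc.get("charges") or {}).items():
        ff.charges[str(cls)] = float(q)
    for role, t in (doc.get("chain_atom_types") or {}).items():
        ff.chain_atom_types[str(role)] = str(t)
    ff.validate()
    return ff


def write_parameters(ff: ForceFieldParameters, path) -> None:
    """Serialise to the native-config dialect (kJ/mol, nm); load round-trips."""
    doc = {
        "energy_unit": "kJ/mol",
        "length_unit": "nm",
        "elec14_scale": ff.elec14_scale,
        "bonds": [{"types": list(k), "k": v.k, "b0": v.b0}
                  for k, v in sorted(ff.bond_types.items())],
        "angles": [{"types": list(k), "k": v.k, "theta0": v.theta0,
                    "k_ub": v.k_ub, "s0": v.s0}
                   for k, v in sorted(ff.angle_types.items())],
        "dihedrals": [{"types": list(k),
                       "terms": [{"K": t.K, "n": t.n, "phase": t.phase} for t in v]}
                      for k, v in sorted(ff.dihedral_terms.items())],
        "impropers": [{"types": list(k),
                       "terms": [{"K": t.K, "n": t.n, "phase": t.phase} for t in v]}
                      for k, v in sorted(ff.improper_terms.items())],
        "lj": [{"type": k, "eps": v.eps, "rmin_half": v.rmin_half,
                "eps_14": v.eps_14, "rmin_half_14": v.rmin_half_14}
               for k, v in sorted(ff.lj_types.items())],
        "charges": dict(sorted(ff.charges.items())),
        "chain_atom_types": dict(sorted(ff.chain_atom_types.items())),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# charmm-prm-rtf dialect
# ---------------------------------------------------------------------------

_SECTIONS = {"BONDS", "ANGLES", "DIHEDRALS", "IMPROPER", "IMPROPERS", "NONBONDED", "END"}


def _load_charmm(path: Path) -> ForceFieldParameters:
    ff = ForceFieldParameters(energy_unit="kJ/mol", source=str(path))
    section = None
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("!")[0].strip()
        if not line:
            continue
        upper = line.upper()
        head = upper.split()[0]
        if head in _SECTIONS:
            section = "IMPROPER" if head == "IMPROPERS" else head
            continue
        if head in ("MASS", "RESI", "GROUP", "BOND", "DONOR", "ACCEPTOR", "IC",
                    "PATCH", "AUTO", "AUTOGENERATE", "DEFA", "CUTNB", "HBOND"):
            if head == "BOND" and section is None:
                continue  # RTF connectivity, not parameters
            continue
        tok = line.split()
        try:
            if head == "ATOM":
                # RTF charge line: ATOM name type charge
                _, _name, atype, q = tok[:4]
                q = float(q)
                if atype in ff.charges and ff.charges[atype] != q:
                    raise ForceFieldError(
                        f"{path}:{lineno}: conflicting charge for type {atype}")
                ff.charges[atype] = q
            elif section == "BONDS":
                a, b, k, b0 = tok[0], tok[1], float(tok[2]), float(tok[3])
                key = _canon_pair((a, b))
                rec = BondType(k=2.0 * k * KCAL_TO_KJ / ANGSTROM_TO_NM**2,
                               b0=b0 * ANGSTROM_TO_NM)
                if key in ff.bond_types and ff.bond_types[key] != rec:
                    raise ForceFieldError(f"{path}:{lineno}: duplicate bond {key}")
                ff.bond_types[key] = rec
            elif section == "ANGLES":
                a, b, c = tok[0], tok[1], tok[2]
                k, th = float(tok[3]), float(tok[4])
                kub = float(tok[5]) if len(tok) > 5 else 0.0
                s0 = float(tok[6]) if len(tok) > 6 else 0.0
                key = _canon_triple((a, b, c))
                rec = AngleType(k=2.0 * k * KCAL_TO_KJ, theta0=th,
                                k_ub=2.0 * kub * KCAL_TO_KJ / ANGSTROM_TO_NM**2,
                                s0=s0 * ANGSTROM_TO_NM)
                if key in ff.angle_types and ff.angle_types[key] != rec:
                    raise ForceFieldError(f"{path}:{lineno}: duplicate angle {key}")
                ff.angle_types[key] = rec
            elif section in ("DIHEDRALS", "IMPROPER"):
                a, b, c, d = tok[0], tok[1], tok[2], tok[3]
                K, n, ph = float(tok[4]), int(tok[5]), float(tok[6])
                key = _canon_quad((a, b, c, d))
                term = DihedralTerm(K=K * KCAL_TO_KJ, n=max(n, 1), phase=ph % 360.0)
                if n == 0:
                    raise ForceFieldError(
                        f"{path}:{lineno}: harmonic (n=0) impropers unsupported")
                table = ff.dihedral_terms if section == "DIHEDRALS" else ff.improper_terms
                table[key] = table.get(key, ()) + (term,)
            elif section == "NONBONDED":
                name = tok[0]
                eps, rmin2 = float(tok[2]), float(tok[3])
                eps14 = float(tok[5]) if len(tok) > 5 else None
                rmin2_14 = float(tok[6]) if len(tok) > 6 else None
                rec = LJType(
                    eps=abs(eps) * KCAL_TO_KJ, rmin_half=rmin2 * ANGSTROM_TO_NM,
                    eps_14=None if eps14 is None else abs(eps14) * KCAL_TO_KJ,
                    rmin_half_14=None if rmin2_14 is None else rmin2_14 * ANGSTROM_TO_NM)
                if name in ff.lj_types and ff.lj_types[name] != rec:
                    raise ForceFieldError(f"{path}:{lineno}: duplicate NONBONDED {name}")
                ff.lj_types[name] = rec
            # anything else outside a known section is ignored RTF furniture
        except (IndexError, ValueError) as exc:
            if isinstance(exc, ForceFieldError):
                raise
            raise ForceFieldError(f"{path}:{lineno}: malformed record {line!r}") from exc
    ff.validate()
    return ff


def load_parameters(path, dialect: str = "native-config") -> ForceFieldParameters:
    """Load and unit-normalise a parameter file.

    Parameters
    ----------
    path : path-like
    dialect : {"native-config", "charmm-prm-rtf"}
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if dialect == "native-config":
        return _load_native(p)
    if dialect == "charmm-prm-rtf":
        return _load_charmm(p)
    raise ForceFieldError(f"unknown dialect {dialect!r}")


def with_zeroed_terms(ff: ForceFieldParameters) -> ForceFieldParameters:
    """Copy with every energetic constant zeroed (geometry preserved)."""
    out = copy.deepcopy(ff)
    out.bond_types = {k: BondType(0.0, v.b0) for k, v in ff.bond_types.items()}
    out.angle_types = {k: AngleType(0.0, v.theta0, 0.0, v.s0)
                       for k, v in ff.angle_types.items()}
    out.dihedral_terms = {k: tuple(DihedralTerm(0.0, t.n, t.phase) for t in v)
                          for k, v in ff.dihedral_terms.items()}
    out.improper_terms = {k: tuple(DihedralTerm(0.0, t.n, t.phase) for t in v)
                          for k, v in ff.improper_terms.items()}
    out.lj_types = {k: LJType(0.0, v.rmin_half, 0.0 if v.eps_14 is not None else None,
                              v.rmin_half_14) for k, v in ff.lj_types.items()}
    out.charges = {k: 0.0 for k in ff.charges}
    return out
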