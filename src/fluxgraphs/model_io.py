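"""Metabolic model container and readers/writers.

A metabolic network of *n* metabolites and *m* reactions is represented by its
signed stoichiometric matrix ``S`` (``S[i, j]`` = net molecules of metabolite
``i`` produced by reaction ``j``), a binary reversibility vector ``r``, flux
bounds ``lb``/``ub`` in mmol/gDW/h, and a 0/1 objective indicator ``c`` (the
biomass reaction in standard FBA usage).

Supported on-disk formats:

* SBML Level 3 with the ``fbc`` package (read through cobrapy/libSBML),
* BiGG-style JSON (read through cobrapy),
* a minimal TSV triplet format (``<base>.stoich.tsv``, ``<base>.reactions.tsv``
  and ``<base>.metabolites.tsv``) used for fixtures and round-tripping, so
  tests never require SBML tooling.
"""

from __future__ import annotations

import gzip
import importlib.resources
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MetabolicModel",
    "FormatError",
    "ValidationError",
    "load_model",
    "load_e_coli_core",
    "validate_model",
    "write_tsv",
]


class FormatError(ValueError):
    """A model file could not be parsed in the declared format."""


class ValidationError(ValueError):
    """A parsed model violates a structural invariant (e.g. duplicate ids)."""


@dataclass
class MetabolicModel:
    """In-memory genome-scale metabolic model.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Unique identifiers; their lengths fix ``n`` and ``m``.
    S
        ``n x m`` signed stoichiometric matrix.
    r
        Length-``m`` binary reversibility vector (1 = reversible).
    lb, ub
        Flux bounds, mmol/gDW/h. Bounds may encode directionality
        independently of ``r``; an irreversible flag with a negative lower
        bound is legal here and flagged by :func:`validate_model`.
    c
        Objective indicator (1 at the objective reaction).
    subsystem
        Optional reaction id -> pathway label map.
    compartment
        Optional metabolite id -> compartment label map.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    r: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    subsystem: dict[str, str] = field(default_factory=dict)
    compartment: dict[str, str] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.r = np.asarray(self.r, dtype=int)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        n, m = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (n, m):
            raise ValidationError(
                f"S has shape {self.S.shape}, expected ({n}, {m})"
            )
        for vec, nm, ln in (
            (self.r, "r", m), (self.lb, "lb", m), (self.ub, "ub", m), (self.c, "c", m)
        ):
            if vec.shape != (ln,):
                raise ValidationError(f"{nm} has length {vec.shape}, expected {ln}")
        if len(set(self.metabolite_ids)) != n:
            raise ValidationError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != m:
            raise ValidationError("duplicate reaction ids")
        if not np.isin(self.r, (0, 1)).all():
            raise ValidationError("r entries must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.metabolite_ids)

    @property
    def m(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def metabolite_index(self, mid: str) -> int:
        return self.metabolite_ids.index(mid)


def _from_cobra(cmodel, name: str = "") -> MetabolicModel:
    """Convert a cobrapy model, dropping boundary metabolites.

    Boundary species ("_b" suffix or SBML boundaryCondition) sit outside the
    mass balance and are removed from the rows of S; exchange pseudo-reactions
    are kept as ordinary columns. Reversibility is taken from the bounds
    (cobrapy folds the SBML reversible flag into the bounds on read).
    """
    mets = [x for x in cmodel.metabolites
            if not getattr(x, "boundary_condition", False)
            and not x.id.endswith("_b")]
    met_ids = [x.id for x in mets]
    rxn_ids = [rx.id for rx in cmodel.reactions]
    midx = {mid: i for i, mid in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rx in enumerate(cmodel.reactions):
        for met, coef in rx.metabolites.items():
            i = midx.get(met.id)
            if i is not None:
                S[i, j] = coef
    lb = np.array([rx.lower_bound for rx in cmodel.reactions])
    ub = np.array([rx.upper_bound for rx in cmodel.reactions])
    r = (lb < 0).astype(int)
    c = np.array([float(rx.objective_coefficient != 0) for rx in cmodel.reactions])
    subsystem = {rx.id: rx.subsystem for rx in cmodel.reactions if rx.subsystem}
    compartment = {x.id: (x.compartment or "") for x in mets}
    return MetabolicModel(met_ids, rxn_ids, S, r, lb, ub, c,
                          subsystem=subsystem, compartment=compartment,
                          name=name or cmodel.id or "")


def _infer_format(path: Path) -> str:
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".xml", ".sbml", ".xml.gz", ".sbml.gz")):
        return "sbml"
    if suffixes.endswith(".json"):
        return "bigg_json"
    if suffixes.endswith(".tsv") or path.is_dir():
        return "tsv_triplet"
    raise FormatError(f"cannot infer model format from {path.name!r}")


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a metabolic model from SBML, BiGG JSON or the TSV triplet format.

    Raises :class:`FormatError` on parse failure, naming the offending file or
    element, and :class:`ValidationError` on duplicate identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "sbml":
        import cobra.io

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmodel = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # libsbml raises a zoo of error types
            raise FormatError(f"SBML parse failure in {path.name}: {exc}") from exc
        return _from_cobra(cmodel, name=path.stem)
    if fmt == "bigg_json":
        import cobra.io

        try:
            cmodel = cobra.io.load_json_model(str(path))
        except Exception as exc:
            raise FormatError(f"BiGG JSON parse failure in {path.name}: {exc}") from exc
        return _from_cobra(cmodel, name=path.stem)
    if fmt == "tsv_triplet":
        return _load_tsv(path)
    raise FormatError(f"unknown model format {fmt!r}")


# --- TSV triplet format -----------------------------------------------------
#
# <base>.stoich.tsv      metabolite  reaction  coefficient
# <base>.reactions.tsv   reaction  lb  ub  reversible  objective  subsystem
# <base>.metabolites.tsv metabolite  compartment

def _tsv_base(path: Path) -> Path:
    s = str(path)
    for suffix in (".stoich.tsv", ".reactions.tsv", ".metabolites.tsv"):
        if s.endswith(suffix):
            return Path(s[: -len(suffix)])
    return path


def _load_tsv(path: Path) -> MetabolicModel:
    base = _tsv_base(path)
    stoich_p = Path(str(base) + ".stoich.tsv")
    rxn_p = Path(str(base) + ".reactions.tsv")
    met_p = Path(str(base) + ".metabolites.tsv")
    if not stoich_p.exists() or not rxn_p.exists():
        raise FormatError(f"TSV triplet incomplete at base {base.name!r}")
    try:
        stoich = pd.read_csv(stoich_p, sep="\t", comment="#")
        rxns = pd.read_csv(rxn_p, sep="\t", comment="#")
    except Exception as exc:
        raise FormatError(f"TSV parse failure at {base.name}: {exc}") from exc
    for col in ("metabolite", "reaction", "coefficient"):
        if col not in stoich.columns:
            raise FormatError(f"{stoich_p.name}: missing column {col!r}")
    for col in ("reaction", "lb", "ub", "reversible", "objective"):
        if col not in rxns.columns:
            raise FormatError(f"{rxn_p.name}: missing column {col!r}")
    rxn_ids = rxns["reaction"].astype(str).tolist()
    if len(set(rxn_ids)) != len(rxn_ids):
        raise ValidationError(f"{rxn_p.name}: duplicate reaction ids")
    compartment: dict[str, str] = {}
    if met_p.exists():
        mets_tab = pd.read_csv(met_p, sep="\t", comment="#")
        met_ids = mets_tab["metabolite"].astype(str).tolist()
        if "compartment" in mets_tab.columns:
            compartment = dict(
                zip(met_ids, mets_tab["compartment"].fillna("").astype(str))
            )
    else:
        met_ids = list(dict.fromkeys(stoich["metabolite"].astype(str)))
    if len(set(met_ids)) != len(met_ids):
        raise ValidationError(f"{met_p.name}: duplicate metabolite ids")
    midx = {mid: i for i, mid in enumerate(met_ids)}
    jidx = {rid: j for j, rid in enumerate(rxn_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for mid, rid, coef in stoich.itertuples(index=False):
        mid, rid = str(mid), str(rid)
        if mid not in midx:
            raise FormatError(f"{stoich_p.name}: unknown metabolite {mid!r}")
        if rid not in jidx:
            raise FormatError(f"{stoich_p.name}: unknown reaction {rid!r}")
        S[midx[mid], jidx[rid]] = float(coef)
    subsystem = {}
    if "subsystem" in rxns.columns:
        subsystem = {
            rid: str(s) for rid, s in zip(rxn_ids, rxns["subsystem"].fillna(""))
            if str(s)
        }
    return MetabolicModel(
        met_ids, rxn_ids, S,
        r=rxns["reversible"].to_numpy(dtype=int),
        lb=rxns["lb"].to_numpy(dtype=float),
        ub=rxns["ub"].to_numpy(dtype=float),
        c=rxns["objective"].to_numpy(dtype=float),
        subsystem=subsystem, compartment=compartment, name=base.name,
    )


def write_tsv(model: MetabolicModel, base: str | Path) -> list[Path]:
    """Write a model as the TSV triplet; returns the three paths written.

    Coefficients and bounds are formatted with ``repr`` round-trip precision so
    write-then-load reproduces S, r, lb, ub exactly.
    """
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        (model.metabolite_ids[i], model.reaction_ids[j], np.format_float_scientific(model.S[i, j], unique=True))
        for i, j in zip(*np.nonzero(model.S))
    ]
    stoich_p = Path(str(base) + ".stoich.tsv")
    pd.DataFrame(rows, columns=["metabolite", "reaction", "coefficient"]).to_csv(
        stoich_p, sep="\t", index=False
    )
    rxn_p = Path(str(base) + ".reactions.tsv")
    pd.DataFrame({
        "reaction": model.reaction_ids,
        "lb": [np.format_float_scientific(x, unique=True) for x in model.lb],
        "ub": [np.format_float_scientific(x, unique=True) for x in model.ub],
        "reversible": model.r,
        "objective": model.c,
        "subsystem": [model.subsystem.get(rid, "") for rid in model.reaction_ids],
    }).to_csv(rxn_p, sep="\t", index=False)
    met_p = Path(str(base) + ".metabolites.tsv")
    pd.DataFrame({
        "metabolite": model.metabolite_ids,
        "compartment": [model.compartment.get(mid, "") for mid in model.metabolite_ids],
    }).to_csv(met_p, sep="\t", index=False)
    return [stoich_p, rxn_p, met_p]


def validate_model(model: MetabolicModel) -> list[str]:
    """Report structural findings (informational, never exceptions).

    Flags empty rows/columns, bound inversions, and metabolites that are never
    produced or never consumed. The latter are legal — the graph constructions
    handle them through the pseudoinverse convention — but often indicate
    model truncation.
    """
    findings: list[str] = []
    col_nonzero = np.count_nonzero(model.S, axis=0)
    row_nonzero = np.count_nonzero(model.S, axis=1)
    for j in np.flatnonzero(col_nonzero == 0):
        findings.append(f"empty reaction column: {model.reaction_ids[j]}")
    for i in np.flatnonzero(row_nonzero == 0):
        findings.append(f"unused metabolite: {model.metabolite_ids[i]}")
    for j in np.flatnonzero(model.lb > model.ub):
        findings.append(f"bound inversion at {model.reaction_ids[j]}")
    # production/consumption over unfolded directions: a reversible reaction
    # both produces and consumes each of its metabolites
    prod = ((model.S > 0) | ((model.S != 0) & (model.r == 1))).any(axis=1)
    cons = ((model.S < 0) | ((model.S != 0) & (model.r == 1))).any(axis=1)
    for i in np.flatnonzero(~prod & (row_nonzero > 0)):
        findings.append(f"metabolite never produced: {model.metabolite_ids[i]}")
    for i in np.flatnonzero(~cons & (row_nonzero > 0)):
        findings.append(f"metabolite never consumed: {model.metabolite_ids[i]}")
    for j in np.flatnonzero((model.r == 0) & (model.lb < 0)):
        findings.append(
            f"irreversible flag with negative lower bound at {model.reaction_ids[j]}"
        )
    return findings


def load_e_coli_core() -> MetabolicModel:
    """Load the *E. coli* core metabolic model (72 metabolites, 95 reactions).

    Uses the copy of the model distributed with cobrapy and restores two pieces
    of the canonical BiGG/COBRA distribution that the bundled SBML omits:

    * all 20 exchange pseudo-reactions are marked reversible (in the original
      MATLAB distribution their bounds are open by default, so they unfold into
      forward and reverse direction nodes: 95 + 59 = 154 unfolded columns);
    * the 11-pathway subsystem annotation, shipped with this package as a
      transcribed TSV table.

    FBA bounds are left exactly as distributed (glucose uptake 10 mmol/gDW/h,
    ATPM lower bound 8.39); scenarios override them explicitly.
    """
    import cobra.io

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmodel = cobra.io.load_model("textbook")
    model = _from_cobra(cmodel, name="e_coli_core")
    for j, rid in enumerate(model.reaction_ids):
        if rid.startswith("EX_"):
            model.r[j] = 1
    ref = importlib.resources.files("fluxgraphs.data") / "e_coli_core_subsystems.tsv"
    tab = pd.read_csv(str(ref), sep="\t", comment="#")
    model.subsystem = dict(zip(tab["reaction"], tab["subsystem"]))
    missing = set(model.reaction_ids) - set(model.subsystem)
    if missing:
        raise ValidationError(f"subsystem table incomplete: {sorted(missing)}")
    return model
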