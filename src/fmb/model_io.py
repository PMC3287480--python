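"""Metabolic models, experimental constraints, perturbations, and their file formats.

A model is the LP substrate for constraint-based flux analysis: a stoichiometric
matrix ``S`` (metabolites x reactions), flux bounds ``alpha``/``beta`` per
reaction (mmol/gDCW/h), and a designated biomass pseudo-reaction. Two formats
are supported: SBML (read-only, through cobrapy) and a plain-TSV dialect with
human-readable reaction equations that round-trips losslessly.

Sign convention: uptake exchange fluxes are negative, e.g. a glucose
phosphotransferase uptake of 3.04 mmol/gDCW/h is recorded as -3.04.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .util import ConstraintError, ModelError

_DEFAULT_BOUND = 1000.0

CONDITIONS = ("control", "perturbed")
CONSTRAINT_CLASSES = ("C13", "FMT")


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str = ""
    subsystem: str = ""
    reversible: bool = True
    lower_bound: float = -_DEFAULT_BOUND
    upper_bound: float = _DEFAULT_BOUND


@dataclass
class MetabolicModel:
    """Stoichiometric model: ``S`` is metabolites (rows) x reactions (columns)."""

    metabolites: list[str]
    reactions: list[Reaction]
    S: np.ndarray
    biomass_reaction_id: str | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.validate()

    # -- index helpers -------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r.id: j for j, r in enumerate(self.reactions)}

    @property
    def lower_bounds(self) -> np.ndarray:
        return np.array([r.lower_bound for r in self.reactions])

    @property
    def upper_bounds(self) -> np.ndarray:
        return np.array([r.upper_bound for r in self.reactions])

    def is_exchange(self, reaction_id: str) -> bool:
        """A reaction touching a single metabolite (boundary pseudo-reaction)."""
        j = self.reaction_index[reaction_id]
        return int(np.count_nonzero(self.S[:, j])) == 1

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        n_met, n_rxn = self.S.shape
        if n_met != len(self.metabolites) or n_rxn != len(self.reactions):
            raise ModelError(
                f"S has shape {self.S.shape} but model lists "
                f"{len(self.metabolites)} metabolites and {len(self.reactions)} reactions"
            )
        seen: set[str] = set()
        for r in self.reactions:
            if r.id in seen:
                raise ModelError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
        for j, r in enumerate(self.reactions):
            if r.lower_bound > r.upper_bound:
                raise ModelError(f"reaction {r.id!r}: lower bound {r.lower_bound} > upper bound {r.upper_bound}")
            if not r.reversible and r.lower_bound < 0:
                raise ModelError(f"irreversible reaction {r.id!r} has negative lower bound")
            if not np.any(self.S[:, j]):
                raise ModelError(f"reaction {r.id!r} has an empty stoichiometry column")
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in seen:
            raise ModelError(f"biomass reaction {self.biomass_reaction_id!r} not in model")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            S=self.S.copy(),
            biomass_reaction_id=self.biomass_reaction_id,
        )


@dataclass(frozen=True)
class ConstraintEntry:
    reaction_id: str
    condition: str
    mean: float
    sigma: float
    constraint_class: str  # "C13" (isotope-traced flux) or "FMT" (culture rate)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConstraintError(f"{self.reaction_id}: negative sigma {self.sigma}")
        if self.condition not in CONDITIONS:
            raise ConstraintError(f"{self.reaction_id}: unknown condition {self.condition!r}")
        if self.constraint_class not in CONSTRAINT_CLASSES:
            raise ConstraintError(f"{self.reaction_id}: unknown class {self.constraint_class!r}")


@dataclass
class ExperimentalConstraints:
    """Measured fluxes (mean +/- sigma) constraining the flux analysis."""

    entries: list[ConstraintEntry] = field(default_factory=list)

    def for_condition(self, condition: str) -> list[ConstraintEntry]:
        if condition not in CONDITIONS:
            raise ConstraintError(f"unknown condition {condition!r}")
        return [e for e in self.entries if e.condition == condition]

    def reaction_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.reaction_id, None)
        return list(seen)

    def validate_against(self, model: MetabolicModel) -> None:
        index = model.reaction_index
        missing = [rid for rid in self.reaction_ids() if rid not in index]
        if missing:
            raise ConstraintError(f"constrained reactions absent from model: {missing}")


@dataclass(frozen=True)
class PerturbationSpec:
    """Reactions forced to zero flux (e.g. reactions lost with a gene knockout)."""

    knockout_reaction_ids: tuple[str, ...] = ()
    label: str = "perturbed"

    @staticmethod
    def from_ids(ids: Iterable[str], label: str = "perturbed") -> "PerturbationSpec":
        return PerturbationSpec(tuple(ids), label)


def apply_knockout(model: MetabolicModel, spec: PerturbationSpec) -> MetabolicModel:
    """Return a copy of *model* with knockout reaction bounds pinned to (0, 0)."""
    index = model.reaction_index
    missing = [rid for rid in spec.knockout_reaction_ids if rid not in index]
    if missing:
        raise ModelError(f"knockout ids not in model: {missing}")
    out = model.copy()
    for rid in spec.knockout_reaction_ids:
        j = index[rid]
        out.reactions[j] = replace(out.reactions[j], lower_bound=0.0, upper_bound=0.0)
    return out


# ---------------------------------------------------------------------------
# TSV model dialect
# ---------------------------------------------------------------------------
# Columns: reaction_id, equation, lower_bound, upper_bound, subsystem.
# Equation grammar: "coef met + coef met ... -> products" with "<->" marking a
# reversible reaction; a missing coefficient means 1; either side may be empty
# (exchange / sink pseudo-reactions).

_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def _parse_side(side: str, line_no: int) -> list[tuple[str, float]]:
    side = side.strip()
    if not side:
        return []
    out = []
    for term in side.split("+"):
        term = term.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise ModelError(f"line {line_no}: cannot parse term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        out.append((m.group(2), coef))
    return out


def parse_equation(equation: str, line_no: int = 0) -> tuple[dict[str, float], bool]:
    """Parse an equation string into {metabolite: coefficient} and reversibility."""
    if "<->" in equation:
        sep, reversible = "<->", True
    elif "->" in equation:
        sep, reversible = "->", False
    else:
        raise ModelError(f"line {line_no}: equation {equation!r} lacks '->' or '<->'")
    left, _, right = equation.partition(sep)
    coeffs: dict[str, float] = {}
    for met, c in _parse_side(left, line_no):
        coeffs[met] = coeffs.get(met, 0.0) - c
    for met, c in _parse_side(right, line_no):
        coeffs[met] = coeffs.get(met, 0.0) + c
    coeffs = {m: c for m, c in coeffs.items() if c != 0.0}
    if not coeffs:
        raise ModelError(f"line {line_no}: equation {equation!r} has empty net stoichiometry")
    return coeffs, reversible


def _format_coef(c: float) -> str:
    return f"{int(c)}" if float(c).is_integer() else repr(c)


def format_equation(model: MetabolicModel, reaction_id: str) -> str:
    j = model.reaction_index[reaction_id]
    col = model.S[:, j]
    lhs, rhs = [], []
    for i, c in enumerate(col):
        if c == 0:
            continue
        met = model.metabolites[i]
        mag = abs(c)
        term = met if mag == 1 else f"{_format_coef(mag)} {met}"
        (lhs if c < 0 else rhs).append(term)
    arrow = "<->" if model.reactions[j].reversible else "->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


def read_model_tsv(path: str | Path, biomass_reaction_id: str | None = None) -> MetabolicModel:
    path = Path(path)
    metabolites: list[str] = []
    met_seen: set[str] = set()
    reactions: list[Reaction] = []
    columns: list[dict[str, float]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ModelError(f"{path}: empty file")
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 4:
                raise ModelError(f"{path} line {line_no}: expected >=4 columns, got {len(row)}")
            rid, equation, lb, ub = row[0].strip(), row[1], row[2], row[3]
            subsystem = row[4].strip() if len(row) > 4 else ""
            if any(r.id == rid for r in reactions):
                raise ModelError(f"{path} line {line_no}: duplicate reaction id {rid!r}")
            coeffs, reversible = parse_equation(equation, line_no)
            for met in coeffs:
                if met not in met_seen:
                    met_seen.add(met)
                    metabolites.append(met)
            if "BIOMASS" in rid.upper() and biomass_reaction_id is None:
                biomass_reaction_id = rid
            reactions.append(
                Reaction(rid, subsystem=subsystem, reversible=reversible,
                         lower_bound=float(lb), upper_bound=float(ub))
            )
            columns.append(coeffs)
    S = np.zeros((len(metabolites), len(reactions)))
    met_index = {m: i for i, m in enumerate(metabolites)}
    for j, coeffs in enumerate(columns):
        for met, c in coeffs.items():
            S[met_index[met], j] = c
    return MetabolicModel(metabolites, reactions, S, biomass_reaction_id)


def write_model_tsv(model: MetabolicModel, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["reaction_id", "equation", "lower_bound", "upper_bound", "subsystem"])
        for r in model.reactions:
            w.writerow([r.id, format_equation(model, r.id),
                        _format_coef(r.lower_bound), _format_coef(r.upper_bound), r.subsystem])


# ---------------------------------------------------------------------------
# SBML (read-only; cobrapy does the parsing)
# ---------------------------------------------------------------------------

def read_sbml(path: str | Path, biomass_reaction_id: str | None = None) -> MetabolicModel:
    """Read an SBML level 2/3 model, preserving the file's reaction order.

    Bounds absent in the file fall back to the conventional FBA defaults
    (-1000/1000 reversible, 0/1000 irreversible); cobrapy applies these
    itself when the SBML carries no explicit bounds.
    """
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise ModelError("SBML support requires cobrapy (pip install fmb[sbml])") from exc
    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise ModelError(f"cannot parse SBML file {path}: {exc}") from exc
    metabolites = [m.id for m in cm.metabolites]
    met_index = {m: i for i, m in enumerate(metabolites)}
    reactions: list[Reaction] = []
    S = np.zeros((len(metabolites), len(cm.reactions)))
    for j, rxn in enumerate(cm.reactions):
        lb, ub = float(rxn.lower_bound), float(rxn.upper_bound)
        reactions.append(
            Reaction(rxn.id, name=rxn.name or "", subsystem=rxn.subsystem or "",
                     reversible=lb < 0, lower_bound=lb, upper_bound=ub)
        )
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = float(coef)
    if biomass_reaction_id is None:
        objective = [r.id for r in cm.reactions if r.objective_coefficient]
        if len(objective) == 1:
            biomass_reaction_id = objective[0]
    return MetabolicModel(metabolites, reactions, S, biomass_reaction_id)


# ---------------------------------------------------------------------------
# Constraint tables (CSV: reaction_id, condition, mean, sigma, class)
# ---------------------------------------------------------------------------

def load_constraints(path: str | Path) -> ExperimentalConstraints:
    path = Path(path)
    entries: list[ConstraintEntry] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"reaction_id", "condition", "mean", "sigma", "class"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ConstraintError(f"{path}: header must contain {sorted(required)}")
        for row in reader:
            entries.append(
                ConstraintEntry(
                    reaction_id=row["reaction_id"].strip(),
                    condition=row["condition"].strip(),
                    mean=float(row["mean"]),
                    sigma=float(row["sigma"]),
                    constraint_class=row["class"].strip(),
                )
            )
    return ExperimentalConstraints(entries)


def write_constraints(constraints: ExperimentalConstraints, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["reaction_id", "condition", "mean", "sigma", "class"])
        for e in constraints.entries:
            w.writerow([e.reaction_id, e.condition, repr(e.mean), repr(e.sigma), e.constraint_class])


def table1_constraints_path() -> Path:
    """Packaged fixture: the measured E. coli wild-type / lpdA-mutant fluxes."""
    return Path(__file__).parent / "data" / "ecoli_lpda_constraints.csv"


def load_table1_constraints() -> ExperimentalConstraints:
    return load_constraints(table1_constraints_path())
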