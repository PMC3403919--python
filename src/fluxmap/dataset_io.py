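"""Structured flux-data template: in-memory model, parser and writer.

A flux experiment bundles six kinds of information: free-form metadata,
the experimental conditions, the timepoints (samples), the substance
weights (traced atoms per molecule, e.g. carbon counts; all 1 for mass
fluxes), the reaction equations, and the flux measurements with optional
per-measurement quality values.

Two on-disk dialects carry the same sectioned layout: a UTF-8 CSV and a
single-sheet xlsx workbook.  Sections are introduced by a header row whose
first cell is one of ``#METADATA``, ``#CONDITIONS``, ``#TIMEPOINTS``,
``#WEIGHTS``, ``#REACTIONS``, ``#FLUXES``.

Reaction equations use a small arrow grammar::

    0.5 Glc + ATP_c -> G6P + ADP_c

Each side is a ``+``-separated list of terms; a term is an optional
decimal stoichiometry, *separated by whitespace* from the metabolite
label.  A number glued to letters (``2Suc``) is deliberately parsed as
the literal label ``2Suc`` with stoichiometry 1: that keeps the grammar
unambiguous and makes this common typo class detectable later, at balance
validation, instead of being silently mis-read.
"""

from __future__ import annotations

import csv
import io
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Iterable, Sequence, TextIO, Union

from .errors import (
    CrossReferenceError,
    DuplicateReactant,
    IOFailure,
    MalformedEquation,
    MissingWeightError,
    TemplateFormatError,
    ValidationError,
)

__all__ = [
    "ReactionEquation",
    "Measurement",
    "FluxExperiment",
    "parse_reaction_equation",
    "format_reaction_equation",
    "parse_template",
    "write_template",
    "SECTION_NAMES",
]

SECTION_NAMES = (
    "#METADATA",
    "#CONDITIONS",
    "#TIMEPOINTS",
    "#WEIGHTS",
    "#REACTIONS",
    "#FLUXES",
)

# '-->' must precede '->' in the alternation so it counts as one arrow.
_ARROW_RE = re.compile(r"-->|->|=>|→")
# optional sign is accepted so that '-1 A' is rejected as stoichiometry <= 0
# rather than silently becoming a label.
_STOICH_TERM_RE = re.compile(r"^([+-]?\d+(?:\.\d+)?)\s+(\S.*)$")


@dataclass(frozen=True)
class ReactionEquation:
    """A named reaction: two sides of (metabolite label, stoichiometry) terms.

    Stoichiometries are positive reals (non-integer values are allowed).
    A label may appear on both sides (exchange-style reactions) but not
    twice on the same side.
    """

    name: str
    reactants: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not str(self.name).strip():
            raise ValidationError("reaction name must be non-empty")
        for side_name, side in (("reactant", self.reactants),
                                ("product", self.products)):
            if not side:
                raise ValidationError(
                    f"reaction {self.name!r}: empty {side_name} side")
            seen = set()
            for label, stoich in side:
                if not label or not label.strip() or label != label.strip():
                    raise ValidationError(
                        f"reaction {self.name!r}: bad label {label!r}")
                if not (isinstance(stoich, (int, float))
                        and math.isfinite(stoich) and stoich > 0):
                    raise ValidationError(
                        f"reaction {self.name!r}: stoichiometry {stoich!r} "
                        f"for {label!r} must be a positive finite number")
                if label in seen:
                    raise ValidationError(
                        f"reaction {self.name!r}: duplicate {side_name} "
                        f"{label!r}")
                seen.add(label)

    @property
    def labels(self) -> set[str]:
        """All metabolite labels appearing on either side."""
        return {lab for lab, _ in self.reactants} | \
               {lab for lab, _ in self.products}


@dataclass(frozen=True)
class Measurement:
    """One flux value for a reaction under one (condition, timepoint).

    The sign of ``flux_value`` encodes net direction; ``quality`` is an
    optional per-measurement scalar (confidence-interval width, flux
    variability range, ...).
    """

    reaction_name: str
    condition: str
    timepoint: str
    flux_value: float
    quality: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.flux_value):
            raise ValidationError(
                f"measurement for {self.reaction_name!r}: non-finite flux")
        if self.quality is not None and not math.isfinite(self.quality):
            raise ValidationError(
                f"measurement for {self.reaction_name!r}: non-finite quality")


@dataclass
class FluxExperiment:
    """The parsed template: metadata, design, weights, reactions, fluxes."""

    metadata: dict[str, str] = field(default_factory=dict)
    conditions: list[str] = field(default_factory=list)
    timepoints: list[str] = field(default_factory=list)
    substance_weights: dict[str, int] = field(default_factory=dict)
    reactions: list[ReactionEquation] = field(default_factory=list)
    measurements: list[Measurement] = field(default_factory=list)

    # -- lookups -----------------------------------------------------------

    def metabolite_labels(self) -> list[str]:
        """Distinct metabolite labels in first-appearance order."""
        seen: dict[str, None] = {}
        for rxn in self.reactions:
            for lab, _ in list(rxn.reactants) + list(rxn.products):
                seen.setdefault(lab)
        return list(seen)

    def reaction(self, name: str) -> ReactionEquation:
        for rxn in self.reactions:
            if rxn.name == name:
                return rxn
        raise KeyError(name)

    def measurement_for(self, reaction_name: str, condition: str,
                        timepoint: str) -> Measurement | None:
        for m in self.measurements:
            if (m.reaction_name, m.condition, m.timepoint) == \
                    (reaction_name, condition, timepoint):
                return m
        return None

    def weight(self, label: str) -> int:
        try:
            return self.substance_weights[label]
        except KeyError:
            raise MissingWeightError([label]) from None

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        """Check all cross-references and weight coverage; raise on failure."""
        if not self.conditions:
            raise ValidationError("experiment declares no conditions")
        if not self.timepoints:
            raise ValidationError("experiment declares no timepoints")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValidationError("duplicate condition names")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValidationError("duplicate timepoint names")
        names = [r.name for r in self.reactions]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate reaction names")
        for label, w in self.substance_weights.items():
            if not (isinstance(w, int) and w >= 0):
                raise ValidationError(
                    f"substance weight for {label!r} must be a nonnegative "
                    f"integer, got {w!r}")
            if w == 0:
                warnings.warn(
                    f"substance weight 0 for {label!r}: its edges will "
                    f"carry zero substance flux", stacklevel=2)
        missing = [lab for lab in self.metabolite_labels()
                   if lab not in self.substance_weights]
        if missing:
            raise MissingWeightError(missing)
        rxn_names = set(names)
        seen_keys: set[tuple[str, str, str]] = set()
        for m in self.measurements:
            key = (m.reaction_name, m.condition, m.timepoint)
            if key in seen_keys:
                raise ValidationError(f"duplicate measurement {key}")
            seen_keys.add(key)
            if m.reaction_name not in rxn_names:
                raise CrossReferenceError(
                    f"measurement refers to undeclared reaction "
                    f"{m.reaction_name!r}")
            if m.condition not in self.conditions:
                raise CrossReferenceError(
                    f"measurement refers to undeclared condition "
                    f"{m.condition!r}")
            if m.timepoint not in self.timepoints:
                raise CrossReferenceError(
                    f"measurement refers to undeclared timepoint "
                    f"{m.timepoint!r}")


# ---------------------------------------------------------------------------
# Reaction equation grammar
# ---------------------------------------------------------------------------

def _parse_side(text: str, side_name: str, name: str
                ) -> tuple[tuple[str, float], ...]:
    if not text.strip():
        raise MalformedEquation(
            f"reaction {name!r}: empty {side_name} side")
    terms = []
    seen: set[str] = set()
    for raw in text.split("+"):
        term = raw.strip()
        if not term:
            raise MalformedEquation(
                f"reaction {name!r}: empty term on {side_name} side")
        m = _STOICH_TERM_RE.match(term)
        if m:
            stoich = float(m.group(1))
            label = m.group(2).strip()
            if stoich <= 0:
                raise MalformedEquation(
                    f"reaction {name!r}: stoichiometry {m.group(1)} <= 0")
        else:
            stoich = 1.0
            label = term
        if label in seen:
            raise DuplicateReactant(
                f"reaction {name!r}: {label!r} appears twice on the "
                f"{side_name} side")
        seen.add(label)
        terms.append((label, stoich))
    return tuple(terms)


def parse_reaction_equation(text: str, name: str) -> ReactionEquation:
    """Parse an arrow equation like ``"2 Suc -> Fru + Glc"``.

    Accepted arrows: ``->``, ``=>``, ``→``, ``-->`` (exactly one).
    An omitted stoichiometry defaults to 1.  A leading number *not*
    whitespace-separated from the label (``2Suc``) is part of the label.
    """
    arrows = _ARROW_RE.findall(text)
    if len(arrows) != 1:
        raise MalformedEquation(
            f"reaction {name!r}: expected exactly one arrow, "
            f"found {len(arrows)} in {text!r}")
    lhs, rhs = _ARROW_RE.split(text)
    return ReactionEquation(
        name=name,
        reactants=_parse_side(lhs, "reactant", name),
        products=_parse_side(rhs, "product", name),
    )


def _format_number(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def format_reaction_equation(rxn: ReactionEquation) -> str:
    """Render an equation back to the arrow grammar (normalized ``->``)."""
    def side(terms):
        out = []
        for label, s in terms:
            out.append(label if s == 1 else f"{_format_number(s)} {label}")
        return " + ".join(out)
    return f"{side(rxn.reactants)} -> {side(rxn.products)}"


# ---------------------------------------------------------------------------
# Sectioned template parsing
# ---------------------------------------------------------------------------

PathLike = Union[str, Path]
Source = Union[PathLike, TextIO, BinaryIO]


def _infer_dialect(path: PathLike) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".xlsx", ".xlsm"):
        return "xlsx"
    return "csv"


def _rows_from_csv(source: Source) -> list[list[str]]:
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            data = data.decode("utf-8")
        return [list(r) for r in csv.reader(io.StringIO(data))]
    try:
        with open(source, newline="", encoding="utf-8") as fh:
            return [list(r) for r in csv.reader(fh)]
    except OSError as exc:
        raise IOFailure(f"cannot read template {source!r}: {exc}") from exc


def _rows_from_xlsx(source: Source) -> list[list[str]]:
    import openpyxl

    try:
        wb = openpyxl.load_workbook(source, read_only=True, data_only=True)
    except OSError as exc:
        raise IOFailure(f"cannot read workbook {source!r}: {exc}") from exc
    ws = wb.worksheets[0]
    rows: list[list[str]] = []
    for row in ws.iter_rows(values_only=True):
        cells = ["" if v is None else (str(v) if not isinstance(v, str) else v)
                 for v in row]
        while cells and cells[-1] == "":
            cells.pop()
        rows.append(cells)
    wb.close()
    return rows


def _split_sections(rows: Iterable[Sequence[str]]
                    ) -> dict[str, list[list[str]]]:
    sections: dict[str, list[list[str]]] = {}
    current: str | None = None
    for row in rows:
        if not row or all(not str(c).strip() for c in row):
            continue
        head = str(row[0]).strip()
        if head.startswith("#"):
            if head not in SECTION_NAMES:
                raise TemplateFormatError(f"unknown section header {head!r}")
            if head in sections:
                raise TemplateFormatError(f"duplicate section {head!r}")
            sections[head] = []
            current = head
            continue
        if current is None:
            raise TemplateFormatError(
                f"data row before any section header: {row!r}")
        sections[current].append([str(c) for c in row])
    for required in SECTION_NAMES:
        if required not in sections:
            raise TemplateFormatError(f"missing section {required}")
    return sections


def _parse_float(text: str, context: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise TemplateFormatError(
            f"{context}: {text!r} is not a number") from None


def _parse_weight(text: str, label: str) -> int:
    value = _parse_float(text, f"weight of {label!r}")
    if value < 0 or value != int(value):
        raise TemplateFormatError(
            f"weight of {label!r} must be a nonnegative integer, "
            f"got {text!r}")
    return int(value)


def parse_template(source: Source, dialect: str | None = None
                   ) -> FluxExperiment:
    """Parse a sectioned template (CSV or xlsx) into a :class:`FluxExperiment`.

    The returned experiment has been fully cross-checked: undeclared
    conditions/timepoints raise :class:`CrossReferenceError` and
    metabolites without a weight entry raise :class:`MissingWeightError`
    (listing every offending label) rather than being defaulted.
    """
    if dialect is None:
        if hasattr(source, "read"):
            raise TemplateFormatError(
                "dialect must be given when parsing from a stream")
        dialect = _infer_dialect(source)
    if dialect == "csv":
        rows = _rows_from_csv(source)
    elif dialect == "xlsx":
        rows = _rows_from_xlsx(source)
    else:
        raise TemplateFormatError(f"unknown dialect {dialect!r}")

    sections = _split_sections(rows)

    exp = FluxExperiment()
    for row in sections["#METADATA"]:
        key = row[0].strip()
        exp.metadata[key] = row[1] if len(row) > 1 else ""
    for row in sections["#CONDITIONS"]:
        exp.conditions.append(row[0].strip())
    for row in sections["#TIMEPOINTS"]:
        exp.timepoints.append(row[0].strip())
    for row in sections["#WEIGHTS"]:
        if len(row) < 2:
            raise TemplateFormatError(f"weight row needs 2 cells: {row!r}")
        label = row[0].strip()
        exp.substance_weights[label] = _parse_weight(row[1].strip(), label)
    for row in sections["#REACTIONS"]:
        if len(row) < 2:
            raise TemplateFormatError(f"reaction row needs 2 cells: {row!r}")
        exp.reactions.append(
            parse_reaction_equation(row[1], name=row[0].strip()))
    for row in sections["#FLUXES"]:
        if len(row) < 4:
            raise TemplateFormatError(f"flux row needs >= 4 cells: {row!r}")
        quality: float | None = None
        if len(row) > 4 and row[4].strip() != "":
            quality = _parse_float(row[4].strip(), "quality")
        exp.measurements.append(Measurement(
            reaction_name=row[0].strip(),
            condition=row[1].strip(),
            timepoint=row[2].strip(),
            flux_value=_parse_float(row[3].strip(), "flux value"),
            quality=quality,
        ))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-weight warning not a parse issue
        exp.validate()
    return exp


# ---------------------------------------------------------------------------
# Template writing
# ---------------------------------------------------------------------------

def _template_rows(exp: FluxExperiment) -> list[list[str]]:
    rows: list[list[str]] = [["#METADATA"]]
    rows += [[k, v] for k, v in exp.metadata.items()]
    rows.append(["#CONDITIONS"])
    rows += [[c] for c in exp.conditions]
    rows.append(["#TIMEPOINTS"])
    rows += [[t] for t in exp.timepoints]
    rows.append(["#WEIGHTS"])
    rows += [[lab, str(w)] for lab, w in exp.substance_weights.items()]
    rows.append(["#REACTIONS"])
    rows += [[r.name, format_reaction_equation(r)] for r in exp.reactions]
    rows.append(["#FLUXES"])
    for m in exp.measurements:
        rows.append([m.reaction_name, m.condition, m.timepoint,
                     repr(m.flux_value),
                     "" if m.quality is None else repr(m.quality)])
    return rows


def write_template(experiment: FluxExperiment, destination: PathLike,
                   dialect: str | None = None) -> None:
    """Write an experiment to CSV or xlsx; fails fast on invalid input.

    The emitted file re-parses to an equal experiment (floats are written
    with ``repr`` and therefore round-trip bit-exactly).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        experiment.validate()
    if dialect is None:
        dialect = _infer_dialect(destination)
    rows = _template_rows(experiment)
    try:
        if dialect == "csv":
            with open(destination, "w", newline="", encoding="utf-8") as fh:
                csv.writer(fh, lineterminator="\n").writerows(rows)
        elif dialect == "xlsx":
            import openpyxl

            wb = openpyxl.Workbook()
            ws = wb.active
            ws.title = "fluxmap"
            for row in rows:
                ws.append(row if row else [""])
            wb.save(destination)
        else:
            raise TemplateFormatError(f"unknown dialect {dialect!r}")
    except OSError as exc:
        raise IOFailure(f"cannot write {destination!r}: {exc}") from exc
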