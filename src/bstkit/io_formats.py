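"""Model file readers and writers.

Three formats are supported:

* **TOML** — the recommended declarative format.  A ``[metadata]`` table
  (``author``, ``version``) and a ``[model]`` table with ``dynamic_species``,
  ``static_species``, ``reactions`` (strings like ``"r1::A + 2*B --> C"``;
  an empty side is written ``[]``), ``kinetics`` (strings like
  ``"r1::A,E1,X4^-0.5"`` — the exponent defaults to 1.0 when omitted),
  optional ``stoichiometry`` overrides (``"species::reaction::coeff"``), and
  sub-tables ``alpha``, ``initial``, ``static_values`` mapping names to
  numbers.
* **BST text** — a plain-text dialect with ``#<section>::start`` /
  ``#<section>::end`` markers, ``//`` line comments, and one record per
  line.  Sections: ``dynamic``, ``static``, ``reactions``, ``kinetics``,
  ``stoichiometry``, ``alpha``, ``initial``, ``staticvalues``.
* **JSON archive** (``.json``) — a versioned serialization of a constructed
  :class:`~bstkit.model_core.BSTModel` that round-trips all floating-point
  values bit-exactly.

Both declarative dialects accept the reaction arrow ``-->`` and, for
robustness against typographic transcription, the en-dash variant ``–>``.
"""

from __future__ import annotations

import json
import os
import re
import tomllib
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    BSTModel,
    KineticsRecord,
    ModelValidationError,
    ReactionRecord,
    assemble_matrices,
    validate,
)

__all__ = [
    "ModelDocument",
    "ParseError",
    "build",
    "model_from_document",
    "parse_toml_text",
    "parse_bst_text",
    "write_toml",
    "write_bst",
    "save_model",
    "load_model",
]

ARCHIVE_SCHEMA_VERSION = 1

_ARROW_RE = re.compile(r"-->|–>|->")


class ParseError(ValueError):
    """Malformed model file; message carries a line number where known."""


@dataclass
class ModelDocument:
    """Declarative model content as read from a file, before compilation.

    Record fields keep the file's string syntax so a document can be written
    back losslessly; :func:`model_from_document` compiles it to a
    :class:`~bstkit.model_core.BSTModel`.
    """

    metadata: dict[str, str] = field(default_factory=dict)
    dynamic_species: list[str] = field(default_factory=list)
    static_species: list[str] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    kinetics: list[str] = field(default_factory=list)
    stoichiometry: list[str] = field(default_factory=list)
    alpha: dict[str, float] = field(default_factory=dict)
    initial: dict[str, float] = field(default_factory=dict)
    static_values: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# record-string parsing (shared by both dialects)
# ---------------------------------------------------------------------------

def _parse_side(text: str, where: str) -> list[tuple[str, float]]:
    text = text.strip()
    if text in ("", "[]", "0", "∅"):
        return []
    out = []
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ParseError(f"{where}: empty term in {text!r}")
        if "*" in term:
            coeff_str, _, name = term.partition("*")
            try:
                coeff = float(coeff_str)
            except ValueError:
                raise ParseError(
                    f"{where}: bad stoichiometric coefficient {coeff_str!r}"
                ) from None
        else:
            coeff, name = 1.0, term
        name = name.strip()
        if not name:
            raise ParseError(f"{where}: missing species name in {term!r}")
        out.append((name, coeff))
    return out


def parse_reaction_string(text: str, where: str = "reaction") -> ReactionRecord:
    """Parse ``"name::A + 2*B --> C"`` into a :class:`ReactionRecord`."""
    name, sep, body = text.partition("::")
    if not sep:
        raise ParseError(f"{where}: missing '::' in reaction {text!r}")
    parts = _ARROW_RE.split(body)
    if len(parts) != 2:
        raise ParseError(f"{where}: reaction {text!r} needs exactly one '-->'")
    return ReactionRecord(
        name=name.strip(),
        reactants=_parse_side(parts[0], where),
        products=_parse_side(parts[1], where),
    )


def parse_kinetics_string(text: str, where: str = "kinetics") -> KineticsRecord:
    """Parse ``"name::A,E1,X4^-0.5"``; an omitted exponent means 1.0."""
    name, sep, body = text.partition("::")
    if not sep:
        raise ParseError(f"{where}: missing '::' in kinetics {text!r}")
    deps = []
    body = body.strip()
    if body:
        for term in body.split(","):
            term = term.strip()
            if not term:
                raise ParseError(f"{where}: empty dependency in {text!r}")
            species, caret, exp_str = term.partition("^")
            if caret:
                try:
                    exponent = float(exp_str)
                except ValueError:
                    raise ParseError(
                        f"{where}: bad exponent {exp_str!r} in {text!r}"
                    ) from None
            else:
                exponent = 1.0
            deps.append((species.strip(), exponent))
    return KineticsRecord(reaction=name.strip(), dependencies=deps)


def parse_override_string(text: str, where: str = "stoichiometry") -> tuple[str, str, float]:
    """Parse ``"species::reaction::coefficient"``."""
    parts = text.split("::")
    if len(parts) != 3:
        raise ParseError(f"{where}: override {text!r} needs species::reaction::coeff")
    try:
        coeff = float(parts[2])
    except ValueError:
        raise ParseError(f"{where}: bad coefficient {parts[2]!r}") from None
    return parts[0].strip(), parts[1].strip(), coeff


# ---------------------------------------------------------------------------
# TOML dialect
# ---------------------------------------------------------------------------

def parse_toml_text(text: str) -> ModelDocument:
    """Parse the TOML dialect into a :class:`ModelDocument`."""
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ParseError(f"TOML parse error: {exc}") from exc
    model = data.get("model", {})
    doc = ModelDocument(
        metadata={str(k): str(v) for k, v in data.get("metadata", {}).items()},
        dynamic_species=list(model.get("dynamic_species", [])),
        static_species=list(model.get("static_species", [])),
        reactions=list(model.get("reactions", [])),
        kinetics=list(model.get("kinetics", [])),
        stoichiometry=list(model.get("stoichiometry", [])),
        alpha={k: float(v) for k, v in model.get("alpha", {}).items()},
        initial={k: float(v) for k, v in model.get("initial", {}).items()},
        static_values={k: float(v) for k, v in model.get("static_values", {}).items()},
    )
    return doc


def _toml_escape(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_toml(doc: ModelDocument) -> str:
    """Render a :class:`ModelDocument` in the TOML dialect."""
    lines = ["[metadata]"]
    for k, v in doc.metadata.items():
        lines.append(f"{k} = {_toml_escape(v)}")
    lines += ["", "[model]"]
    for key in ("dynamic_species", "static_species", "reactions", "kinetics",
                "stoichiometry"):
        items = getattr(doc, key)
        rendered = ", ".join(_toml_escape(s) for s in items)
        lines.append(f"{key} = [{rendered}]")
    for key, table in (("alpha", doc.alpha), ("initial", doc.initial),
                       ("static_values", doc.static_values)):
        lines += ["", f"[model.{key}]"]
        for k, v in table.items():
            lines.append(f"{k} = {float(v)!r}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# BST text dialect
# ---------------------------------------------------------------------------

_SECTIONS = {
    "dynamic", "static", "reactions", "kinetics", "stoichiometry",
    "alpha", "initial", "staticvalues",
}


def parse_bst_text(text: str) -> ModelDocument:
    """Parse the plain-text BST dialect into a :class:`ModelDocument`.

    Sections are delimited by ``#<name>::start`` / ``#<name>::end`` markers;
    ``//`` comments run to end of line; blank lines are ignored.
    """
    doc = ModelDocument()
    section: str | None = None
    section_line = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("//", 1)[0].strip()
        if not line:
            continue
        if line.startswith("#"):
            marker = line[1:]
            name, sep, action = marker.partition("::")
            name = name.strip().lower()
            action = action.strip().lower()
            if not sep or action not in ("start", "end"):
                raise ParseError(f"line {lineno}: malformed section marker {raw!r}")
            if name not in _SECTIONS:
                raise ParseError(f"line {lineno}: unknown section {name!r}")
            if action == "start":
                if section is not None:
                    raise ParseError(
                        f"line {lineno}: section {name!r} opened inside "
                        f"{section!r} (opened at line {section_line})"
                    )
                section, section_line = name, lineno
            else:
                if section != name:
                    raise ParseError(
                        f"line {lineno}: '#{name}::end' does not match open "
                        f"section {section!r}"
                    )
                section = None
            continue
        if section is None:
            raise ParseError(f"line {lineno}: record outside any section: {raw!r}")
        where = f"line {lineno}"
        if section == "dynamic":
            doc.dynamic_species.append(line)
        elif section == "static":
            doc.static_species.append(line)
        elif section == "reactions":
            parse_reaction_string(line, where)  # syntax check with line number
            doc.reactions.append(line)
        elif section == "kinetics":
            parse_kinetics_string(line, where)
            doc.kinetics.append(line)
        elif section == "stoichiometry":
            parse_override_string(line, where)
            doc.stoichiometry.append(line)
        else:  # alpha / initial / staticvalues: "name = value"
            key, sep, value = line.partition("=")
            if not sep:
                raise ParseError(f"{where}: expected 'name = value', got {raw!r}")
            try:
                num = float(value)
            except ValueError:
                raise ParseError(f"{where}: bad number {value.strip()!r}") from None
            target = {
                "alpha": doc.alpha,
                "initial": doc.initial,
                "staticvalues": doc.static_values,
            }[section]
            target[key.strip()] = num
    if section is not None:
        raise ParseError(
            f"section {section!r} opened at line {section_line} is never closed "
            f"(missing '#{section}::end')"
        )
    return doc


def write_bst(doc: ModelDocument) -> str:
    """Render a :class:`ModelDocument` in the BST text dialect."""
    out = []
    if doc.metadata:
        for k, v in doc.metadata.items():
            out.append(f"// {k}: {v}")
        out.append("")

    def block(name: str, lines: list[str]) -> None:
        out.append(f"#{name}::start")
        out.extend(lines)
        out.append(f"#{name}::end")
        out.append("")

    block("dynamic", doc.dynamic_species)
    block("static", doc.static_species)
    block("reactions", doc.reactions)
    block("kinetics", doc.kinetics)
    if doc.stoichiometry:
        block("stoichiometry", doc.stoichiometry)
    block("alpha", [f"{k} = {float(v)!r}" for k, v in doc.alpha.items()])
    block("initial", [f"{k} = {float(v)!r}" for k, v in doc.initial.items()])
    block("staticvalues", [f"{k} = {float(v)!r}" for k, v in doc.static_values.items()])
    return "\n".join(out)


# ---------------------------------------------------------------------------
# document -> model
# ---------------------------------------------------------------------------

def model_from_document(doc: ModelDocument) -> BSTModel:
    """Compile a declarative document into a validated :class:`BSTModel`."""
    reactions = [parse_reaction_string(s) for s in doc.reactions]
    kinetics = [parse_kinetics_string(s) for s in doc.kinetics]
    overrides = [parse_override_string(s) for s in doc.stoichiometry]
    S, G = assemble_matrices(
        doc.dynamic_species, doc.static_species, reactions, kinetics, overrides
    )
    names = [r.name for r in reactions]
    for rec in kinetics:
        if rec.reaction not in names:
            raise ModelValidationError(f"kinetics for unknown reaction {rec.reaction!r}")
    for key in doc.alpha:
        if key not in names:
            raise ModelValidationError(f"alpha entry for unknown reaction {key!r}")
    for key in doc.initial:
        if key not in doc.dynamic_species:
            raise ModelValidationError(f"initial entry for unknown species {key!r}")
    for key in doc.static_values:
        if key not in doc.static_species:
            raise ModelValidationError(f"static value for unknown species {key!r}")
    missing = [s for s in doc.static_species if s not in doc.static_values]
    if missing:
        raise ModelValidationError(f"static species without values: {missing}")
    alpha = np.array([doc.alpha.get(name, 0.0) for name in names])
    x0 = np.array([doc.initial.get(s, 0.0) for s in doc.dynamic_species])
    xs = np.array([doc.static_values[s] for s in doc.static_species])
    model = BSTModel(
        dynamic_species=list(doc.dynamic_species),
        static_species=list(doc.static_species),
        reaction_names=names,
        S=S,
        G=G,
        alpha=alpha,
        x0=x0,
        xs=xs,
        metadata=dict(doc.metadata),
    )
    diags = validate(model)
    if diags:
        raise ModelValidationError("; ".join(diags))
    return model


def document_from_model(model: BSTModel) -> ModelDocument:
    """Reconstruct a declarative document from a model's matrices.

    Inverse of :func:`model_from_document` up to record formatting; used to
    emit fixture files.
    """
    doc = ModelDocument(metadata=dict(model.metadata))
    doc.dynamic_species = list(model.dynamic_species)
    doc.static_species = list(model.static_species)
    for k, name in enumerate(model.reaction_names):
        col = model.S[:, k]

        def side(sign):
            terms = []
            for i in np.flatnonzero(sign * col > 0):
                c = float(abs(col[i]))
                sp = model.dynamic_species[i]
                terms.append(sp if c == 1 else f"{c!r}*{sp}")
            return " + ".join(terms) if terms else "[]"

        doc.reactions.append(f"{name}::{side(-1)} --> {side(+1)}")
        deps = [
            f"{model.species[j]}^{float(model.G[j, k])!r}"
            for j in np.flatnonzero(model.G[:, k])
        ]
        if deps:
            doc.kinetics.append(f"{name}::" + ",".join(deps))
        doc.alpha[name] = float(model.alpha[k])
    for i, sp in enumerate(model.dynamic_species):
        doc.initial[sp] = float(model.x0[i])
    for j, sp in enumerate(model.static_species):
        doc.static_values[sp] = float(model.xs[j])
    return doc


# ---------------------------------------------------------------------------
# archive (JSON)
# ---------------------------------------------------------------------------

def save_model(path, model: BSTModel) -> None:
    """Serialize a model to a versioned JSON archive (bit-exact floats)."""
    diags = validate(model)
    if diags:
        raise ModelValidationError("refusing to save invalid model: " + "; ".join(diags))
    payload = {
        "schema_version": ARCHIVE_SCHEMA_VERSION,
        "metadata": model.metadata,
        "dynamic_species": model.dynamic_species,
        "static_species": model.static_species,
        "reaction_names": model.reaction_names,
        "S": model.S.tolist(),
        "G": model.G.tolist(),
        "alpha": model.alpha.tolist(),
        "x0": model.x0.tolist(),
        "xs": model.xs.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> BSTModel:
    """Load a model archive written by :func:`save_model`."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"corrupted model archive {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != ARCHIVE_SCHEMA_VERSION:
        raise ParseError(
            f"archive schema version {version!r} not supported "
            f"(this reader handles version {ARCHIVE_SCHEMA_VERSION})"
        )
    model = BSTModel(
        dynamic_species=list(payload["dynamic_species"]),
        static_species=list(payload["static_species"]),
        reaction_names=list(payload["reaction_names"]),
        S=np.array(payload["S"], dtype=float).reshape(
            len(payload["dynamic_species"]), len(payload["reaction_names"])
        ),
        G=np.array(payload["G"], dtype=float).reshape(
            len(payload["dynamic_species"]) + len(payload["static_species"]),
            len(payload["reaction_names"]),
        ),
        alpha=np.array(payload["alpha"], dtype=float),
        x0=np.array(payload["x0"], dtype=float),
        xs=np.array(payload["xs"], dtype=float),
        metadata=dict(payload.get("metadata", {})),
    )
    diags = validate(model)
    if diags:
        raise ModelValidationError("archive failed validation: " + "; ".join(diags))
    return model


# ---------------------------------------------------------------------------
# build: single entry point, format by extension
# ---------------------------------------------------------------------------

def build(path) -> BSTModel:
    """Construct a validated model from a ``.toml``, ``.bst`` or ``.json`` file."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".toml":
        with open(path) as fh:
            return model_from_document(parse_toml_text(fh.read()))
    if ext == ".bst":
        with open(path) as fh:
            return model_from_document(parse_bst_text(fh.read()))
    if ext == ".json":
        return load_model(path)
    raise ParseError(
        f"unknown model file extension {ext!r} (expected .toml, .bst or .json)"
    )
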