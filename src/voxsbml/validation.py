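"""Syntactic and semantic validation of spatial models.

Validation is offline and built in: structural (core-SBML) checks on
identifiers and references, plus a custom semantic validator for the spatial
constructs — sampled-value uniqueness, domain/compartment mappings, membrane
adjacency arity, interior-point consistency, coordinate bounds — and the
biological-consistency warnings from :mod:`voxsbml.topology`.

Issues are data, not exceptions: each check returns a list of
:class:`Issue` records with a severity, a stable rule id, a message, and the
offending identifier.  An empty list is a pass.  Export refuses on
error-severity issues only; biological impossibility is a warning.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Union

import libsbml
import numpy as np

from .topology import check_biology

__all__ = ["Issue", "validate_syntax", "validate_spatial", "validate_file"]

Severity = Literal["error", "warning"]


@dataclass(frozen=True)
class Issue:
    """One validation finding."""

    severity: Severity
    rule: str
    message: str
    object_id: str = ""

    def __str__(self) -> str:
        ident = f" {self.object_id}" if self.object_id else ""
        return f"{self.severity.upper()} {self.rule}{ident}: {self.message}"


def _err(rule: str, message: str, object_id: str = "") -> Issue:
    return Issue("error", rule, message, object_id)


def _warn(rule: str, message: str, object_id: str = "") -> Issue:
    return Issue("warning", rule, message, object_id)


def validate_file(path) -> list[Issue]:
    """Syntax checks on an SBML file on disk: well-formed XML, declared L3V1,
    and libsbml's own read errors."""
    path = Path(path)
    issues: list[Issue] = []
    if not path.exists():
        return [_err("file-missing", f"no such file: {path}", str(path))]
    doc = libsbml.readSBML(str(path))
    fatal = doc.getNumErrors(libsbml.LIBSBML_SEV_FATAL)
    if fatal or doc.getModel() is None:
        for i in range(doc.getNumErrors()):
            e = doc.getError(i)
            issues.append(
                _err("xml-parse", e.getMessage().strip().splitlines()[0], str(path))
            )
        return issues or [_err("xml-parse", "no model in document", str(path))]
    if (doc.getLevel(), doc.getVersion()) != (3, 1):
        issues.append(
            _err(
                "level-version",
                f"expected SBML Level 3 Version 1, found L{doc.getLevel()}V{doc.getVersion()}",
            )
        )
    for i in range(doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR)):
        issues.append(_err("sbml-read", doc.getError(i).getMessage().strip().splitlines()[0]))
    return issues


def validate_syntax(target) -> list[Issue]:
    """Core structural checks.

    Accepts a :class:`~voxsbml.sbml_spatial.SpatialModel` or a file path.  On a
    model it checks identifier uniqueness and referential integrity: species
    compartments exist, spatial parameters target existing species, reaction
    participants and rate-law identifiers resolve, and rate expressions parse.
    """
    if isinstance(target, (str, Path)):
        return validate_file(target)
    model = target
    issues: list[Issue] = []

    seen: set[str] = set()
    for ident in (
        [s.id for s in model.species]
        + [p.id for p in model.parameters]
        + [r.id for r in model.reactions]
        + model.compartments
    ):
        if ident in seen:
            issues.append(_err("dup-id", "identifier is not unique", ident))
        seen.add(ident)

    compartments = set(model.compartments)
    species_ids = {s.id for s in model.species}
    known = species_ids | {p.id for p in model.parameters} | compartments
    for s in model.species:
        if s.compartment not in compartments:
            issues.append(
                _err("species-compartment", f"compartment {s.compartment!r} does not exist", s.id)
            )
    for p in model.parameters:
        if p.role != "none" and p.species not in species_ids:
            issues.append(
                _err("param-target", f"target species {p.species!r} does not exist", p.id)
            )
    from .sbml_spatial import _MATH_FUNCS, _TOKEN  # shared identifier grammar

    for r in model.reactions:
        for sp in (*r.reactants, *r.products):
            if sp not in species_ids:
                issues.append(
                    _err("reaction-species", f"species {sp!r} does not exist", r.id)
                )
        ast = libsbml.parseL3Formula(r.rate_expression)
        if ast is None:
            issues.append(
                _err("math-parse", f"rate expression {r.rate_expression!r} does not parse", r.id)
            )
            continue
        for tok in _TOKEN.findall(r.rate_expression):
            if tok not in known and tok.lower() not in _MATH_FUNCS:
                issues.append(
                    _err("math-ref", f"unknown identifier {tok!r} in rate expression", r.id)
                )
    return issues


def validate_spatial(model) -> list[Issue]:
    """Custom semantic validation of the spatial constructs.

    Checks, in order: sampled-value uniqueness; every grid value backed by a
    sampled volume; every volume type populated and mapped to exactly one
    compartment; adjacency references resolve; every membrane has exactly two
    adjacency records (enforced by construction, checked anyway); membrane
    dimension is volume dimension − 1 (trivially 2 vs 3 here, flagged if a
    membrane type collides with a volume type); each interior point sits on a
    voxel of its domain's value; coordinate bounds match extent × spacing.
    Biological-consistency warnings from the topology layer are appended.
    """
    issues: list[Issue] = []
    geom = model.geometry
    vm = geom.value_map

    values = list(vm.values())
    for v in sorted(set(values)):
        owners = [t for t, val in vm.items() if val == v]
        if len(owners) > 1:
            issues.append(
                _err("dup-sampled-value", f"sampled value {v} assigned to {owners}", owners[1])
            )

    present = set(int(v) for v in np.unique(geom.grid))
    backed = set(vm.values())
    for v in sorted(present - backed):
        issues.append(_err("orphan-value", f"grid value {v} has no sampled volume"))

    domains_by_type: dict[str, int] = {}
    for d in model.domains:
        domains_by_type[d.domain_type] = domains_by_type.get(d.domain_type, 0) + 1
    for t in geom.depth_order:
        if t in present_types(geom) and domains_by_type.get(t, 0) == 0:
            issues.append(_err("type-no-domain", "volume domain type has no domain", t))

    compartments = set(model.compartments)
    for t in model.domain_types:
        if model.compartment_of(t) not in compartments:
            issues.append(_err("type-no-compartment", "domain type has no compartment", t))

    dom_ids = {d.id for d in model.domains}
    for mem in model.graph.membranes:
        missing = [x for x in (mem.inner, mem.outer) if x not in dom_ids]
        for x in missing:
            issues.append(
                _err("adjacent-unknown", f"adjacency references unknown domain {x!r}", mem.id)
            )
        if mem.domain_type in vm:
            issues.append(
                _err(
                    "membrane-dimension",
                    "membrane domain type collides with a volume type "
                    "(membranes must have dimension 2 = 3 − 1 and no voxels)",
                    mem.domain_type,
                )
            )
        # exactly two adjacency records per membrane: inner and outer
        if mem.inner == mem.outer:
            issues.append(
                _err("membrane-arity", "membrane must join two distinct domains", mem.id)
            )

    for d in model.domains:
        x, y, z = d.interior_point
        inside = all(0 <= c < e for c, e in zip((x, y, z), geom.extents))
        expected = vm.get(d.domain_type)
        if not inside or int(geom.grid[x, y, z]) != expected:
            issues.append(
                _err(
                    "interior-point",
                    f"interior point {d.interior_point} does not carry sampled "
                    f"value {expected} of type {d.domain_type}",
                    d.id,
                )
            )

    # coordinate bounds are derived (extent × spacing) at export; flag
    # non-positive spacing which would corrupt them
    if any(s <= 0 for s in geom.spacing):
        issues.append(_err("coordinate-bounds", f"non-positive spacing {geom.spacing}"))

    depths = {t: i for i, t in enumerate(geom.depth_order)}
    for w in check_biology(model.graph, depths):
        issues.append(_warn("bio-adjacency", w))
    return issues


def present_types(geom) -> set[str]:
    """Volume types actually present in the grid."""
    present = set(int(v) for v in np.unique(geom.grid))
    return {t for t, v in geom.value_map.items() if v in present}
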