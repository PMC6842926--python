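"""Spatial SBML model container, editing operations, and (de)serialization.

A :class:`SpatialModel` bundles the voxel geometry (grid, domains, adjacency
graph with membranes) with the biochemistry a user adds on top — species,
parameters with spatial roles (diffusion, advection, boundary condition), and
reactions.  It serializes to an SBML Level 3 Version 1 document that declares
the Spatial Processes package as required, and can be reconstructed from such
a document, so models survive an export → import round trip bit-exactly at the
geometry level.

Serialization conventions
-------------------------
* The sampled field stores the grid uncompressed, as space-separated integers,
  x-index fastest, then y, then z.
* Voxel (i, j, k) sits at the physical point ((i+0.5)dx, (j+0.5)dy, (k+0.5)dz)
  (voxel-centre convention); interior points are written in these coordinates.
* One compartment per domain type; volume compartments get size
  voxel_count · dx·dy·dz so the document is simulation-ready, membranes get
  dimension 2.
* One sampledVolume per *volume* domain type only — membranes have no sampled
  value, they exist through their adjacentDomains records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import libsbml
import networkx as nx
import numpy as np

from .errors import ExportRefusedError, InputError, SBMLImportError
from .geometry_builder import Domain, LabeledGeometry, label_domains
from .topology import AdjacencyGraph, Membrane

__all__ = [
    "Species",
    "SpatialParameter",
    "Reaction",
    "SpatialModel",
    "build_model",
    "add_species",
    "add_spatial_parameter",
    "add_reaction",
    "export_sbml",
    "import_sbml",
]

SpatialRole = Literal["none", "diffusion", "advection", "boundary-condition"]

_AXES = ("x", "y", "z")
_BOUNDARIES = {"Xmin", "Xmax", "Ymin", "Ymax", "Zmin", "Zmax"}

_COORD_KIND = {
    "x": libsbml.SPATIAL_COORDINATEKIND_CARTESIAN_X,
    "y": libsbml.SPATIAL_COORDINATEKIND_CARTESIAN_Y,
    "z": libsbml.SPATIAL_COORDINATEKIND_CARTESIAN_Z,
}


def sanitize_id(name: str) -> str:
    """Map an arbitrary name onto the SBML SId grammar.

    Non-alphanumeric characters become underscores; a leading digit gets an
    underscore prefix.  ``sanitize_id("nuclear membrane")`` -> ``"nuclear_membrane"``.
    """
    s = re.sub(r"[^A-Za-z0-9_]", "_", name)
    if not s or s[0].isdigit():
        s = "_" + s
    return s


@dataclass(frozen=True)
class Species:
    """A molecular species living in one compartment (volume or membrane)."""

    id: str
    compartment: str
    initial_concentration: float


@dataclass(frozen=True)
class SpatialParameter:
    """A scalar parameter, optionally with a spatial role.

    role "diffusion": diffusion coefficient of ``species`` (isotropic when
    ``axis`` is None, otherwise along one axis); "advection": advection
    coefficient along ``axis`` (required); "boundary-condition": Dirichlet
    value for ``species`` on ``boundary`` (e.g. ``"Xmax"``); "none": an
    ordinary constant.
    """

    id: str
    value: float
    role: SpatialRole = "none"
    species: str | None = None
    axis: str | None = None
    boundary: str | None = None


@dataclass(frozen=True)
class Reaction:
    """A reaction with a rate expression over known identifiers.

    ``membrane_local`` marks a transport reaction that takes place on a
    membrane (e.g. export from cytosol to the extracellular space across the
    plasma membrane); ``compartment`` names that membrane's compartment.
    """

    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_expression: str
    membrane_local: bool = False
    compartment: str | None = None


@dataclass
class SpatialModel:
    """Everything needed to write one spatial SBML document."""

    geometry: LabeledGeometry
    domains: list[Domain]
    graph: AdjacencyGraph
    species: list[Species] = field(default_factory=list)
    parameters: list[SpatialParameter] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    name: str = "spatial_model"
    level: int = 3
    version: int = 1

    # -- derived views ----------------------------------------------------

    @property
    def volume_types(self) -> list[str]:
        return list(self.geometry.depth_order)

    @property
    def membrane_types(self) -> list[str]:
        return sorted(self.graph.membrane_types)

    @property
    def domain_types(self) -> list[str]:
        return self.volume_types + self.membrane_types

    def compartment_of(self, domain_type: str) -> str:
        """Compartment id mapped to a domain type."""
        return sanitize_id(domain_type)

    @property
    def compartments(self) -> list[str]:
        return [self.compartment_of(t) for t in self.domain_types]

    def species_ids(self) -> set[str]:
        return {s.id for s in self.species}

    def parameter_ids(self) -> set[str]:
        return {p.id for p in self.parameters}


def build_model(
    geom: LabeledGeometry,
    domains: list[Domain],
    graph: AdjacencyGraph,
    name: str = "spatial_model",
) -> SpatialModel:
    """Assemble a :class:`SpatialModel` from the geometry pipeline's outputs.

    Raises
    ------
    InputError
        If a domain references a domain type absent from the geometry.
    """
    known = set(geom.value_map)
    for d in domains:
        if d.domain_type not in known:
            raise InputError(
                f"domain {d.id} references unknown domain type {d.domain_type!r}"
            )
    mem_domains = {m.inner for m in graph.membranes} | {m.outer for m in graph.membranes}
    dom_ids = {d.id for d in domains}
    if not mem_domains <= dom_ids:
        raise InputError(
            f"adjacency references unknown domains {sorted(mem_domains - dom_ids)}"
        )
    return SpatialModel(geometry=geom, domains=list(domains), graph=graph, name=name)


# -- editing operations ---------------------------------------------------


def add_species(
    model: SpatialModel, id: str, compartment: str, initial_concentration: float
) -> SpatialModel:
    """Append a species to ``compartment`` (a membrane compartment is allowed:
    the species is then surface-bound).  Returns the model."""
    if id in model.species_ids() or id in model.parameter_ids():
        raise InputError(f"duplicate identifier {id!r}")
    if compartment not in model.compartments:
        raise InputError(
            f"unknown compartment {compartment!r}; have {model.compartments}"
        )
    model.species.append(
        Species(id=id, compartment=compartment, initial_concentration=float(initial_concentration))
    )
    return model


def add_spatial_parameter(
    model: SpatialModel,
    id: str,
    value: float,
    role: SpatialRole = "none",
    species: str | None = None,
    axis: str | None = None,
    boundary: str | None = None,
) -> SpatialModel:
    """Append a parameter, optionally with a spatial role.

    Diffusion is isotropic unless an axis is given; advection requires an
    axis; a boundary condition requires a boundary face (default ``"Xmax"``
    would be arbitrary, so it must be explicit).
    """
    if id in model.parameter_ids() or id in model.species_ids():
        raise InputError(f"duplicate identifier {id!r}")
    if role not in ("none", "diffusion", "advection", "boundary-condition"):
        raise InputError(f"unknown spatial role {role!r}")
    if role != "none":
        if species is None or species not in model.species_ids():
            raise InputError(f"spatial parameter {id!r} targets unknown species {species!r}")
    if role == "advection" and axis not in _AXES:
        raise InputError(f"advection parameter {id!r} requires an axis in {_AXES}")
    if role == "diffusion" and axis is not None and axis not in _AXES:
        raise InputError(f"diffusion axis must be one of {_AXES}, got {axis!r}")
    if role == "boundary-condition":
        if boundary not in _BOUNDARIES:
            raise InputError(
                f"boundary-condition parameter {id!r} requires a boundary in "
                f"{sorted(_BOUNDARIES)}"
            )
    model.parameters.append(
        SpatialParameter(
            id=id, value=float(value), role=role, species=species, axis=axis, boundary=boundary
        )
    )
    return model


_TOKEN = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_MATH_FUNCS = {
    "abs", "exp", "ln", "log", "log10", "sqrt", "pow", "power",
    "sin", "cos", "tan", "piecewise", "floor", "ceil",
    "pi", "exponentiale", "time", "t",
}


def add_reaction(
    model: SpatialModel,
    id: str,
    reactants: Iterable[str],
    products: Iterable[str],
    rate_expression: str,
    membrane_local: bool = False,
    compartment: str | None = None,
) -> SpatialModel:
    """Append a reaction with an infix rate law.

    Every identifier in the expression (and in the reactant/product lists)
    must already exist as a species or parameter; unknown identifiers are
    reported by name.  ``membrane_local=True`` marks a transport reaction
    across a membrane, optionally pinned to that membrane's ``compartment``.
    """
    if any(r.id == id for r in model.reactions):
        raise InputError(f"duplicate reaction id {id!r}")
    known = model.species_ids() | model.parameter_ids() | set(model.compartments)
    reactants = tuple(reactants)
    products = tuple(products)
    for sp in (*reactants, *products):
        if sp not in model.species_ids():
            raise InputError(f"reaction {id!r} references unknown species {sp!r}")
    ast = libsbml.parseL3Formula(rate_expression)
    if ast is None:
        raise InputError(
            f"rate expression {rate_expression!r} does not parse: "
            f"{libsbml.getLastParseL3Error()}"
        )
    for tok in _TOKEN.findall(rate_expression):
        if tok not in known and tok.lower() not in _MATH_FUNCS:
            raise InputError(
                f"rate expression of {id!r} references unknown identifier {tok!r}"
            )
    if compartment is not None and compartment not in model.compartments:
        raise InputError(f"unknown compartment {compartment!r}")
    model.reactions.append(
        Reaction(
            id=id,
            reactants=reactants,
            products=products,
            rate_expression=rate_expression,
            membrane_local=bool(membrane_local),
            compartment=compartment,
        )
    )
    return model


# -- serialization --------------------------------------------------------


def _volume_voxel_counts(model: SpatialModel) -> dict[str, int]:
    counts: dict[str, int] = {t: 0 for t in model.volume_types}
    for d in model.domains:
        counts[d.domain_type] = counts.get(d.domain_type, 0) + d.voxel_count
    return counts


def to_document(model: SpatialModel) -> libsbml.SBMLDocument:
    """Serialize to a libsbml L3V1 document with the spatial package required."""
    ns = libsbml.SpatialPkgNamespaces(3, 1, 1)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("spatial", True)
    m = doc.createModel()
    m.setId(sanitize_id(model.name))

    geom = model.geometry
    nx_, ny_, nz_ = geom.extents
    dx, dy, dz = geom.spacing

    mplug = m.getPlugin("spatial")
    g = mplug.createGeometry()
    g.setCoordinateSystem("cartesian")

    for ax, extent, step in zip(_AXES, (nx_, ny_, nz_), (dx, dy, dz)):
        cc = g.createCoordinateComponent()
        cc.setId(ax)
        cc.setType(_COORD_KIND[ax])
        bmin = cc.createBoundaryMin()
        bmin.setId(f"{ax.upper()}min")
        bmin.setValue(0.0)
        bmax = cc.createBoundaryMax()
        bmax.setId(f"{ax.upper()}max")
        bmax.setValue(extent * step)

    voxel_volume = dx * dy * dz
    counts = _volume_voxel_counts(model)

    # domain types + compartments with mapping
    for tname in model.domain_types:
        is_volume = tname in geom.value_map
        dt = g.createDomainType()
        dt.setId(sanitize_id(tname) + "_domainType")
        dt.setSpatialDimensions(3 if is_volume else 2)

        comp = m.createCompartment()
        comp.setId(model.compartment_of(tname))
        comp.setName(tname)
        comp.setConstant(True)
        comp.setSpatialDimensions(3 if is_volume else 2)
        comp.setSize(counts[tname] * voxel_volume if is_volume else 1.0)
        cmap = comp.getPlugin("spatial").createCompartmentMapping()
        cmap.setId(f"cmap_{sanitize_id(tname)}")
        cmap.setDomainType(dt.getId())
        cmap.setUnitSize(1.0)

    # volume domains with interior points in physical (voxel-centre) coords
    for d in model.domains:
        dom = g.createDomain()
        dom.setId(sanitize_id(d.id))
        dom.setDomainType(sanitize_id(d.domain_type) + "_domainType")
        ip = dom.createInteriorPoint()
        i, j, k = d.interior_point
        ip.setCoord1((i + 0.5) * dx)
        ip.setCoord2((j + 0.5) * dy)
        ip.setCoord3((k + 0.5) * dz)

    # membrane domains + adjacentDomains pairs
    for mem in model.graph.membranes:
        dom = g.createDomain()
        dom.setId(sanitize_id(mem.id))
        dom.setDomainType(sanitize_id(mem.domain_type) + "_domainType")
        for tag, vol in (("inner", mem.inner), ("outer", mem.outer)):
            ad = g.createAdjacentDomains()
            ad.setId(f"adj_{sanitize_id(mem.id)}_{sanitize_id(vol)}")
            ad.setDomain1(sanitize_id(mem.id))
            ad.setDomain2(sanitize_id(vol))

    # sampled-field geometry: one sampledVolume per VOLUME type only
    sfg = g.createSampledFieldGeometry()
    sfg.setId("sampledFieldGeometry")
    sfg.setIsActive(True)
    sfg.setSampledField("sampledField")
    for tname in model.volume_types:
        sv = sfg.createSampledVolume()
        sv.setId(f"sv_{sanitize_id(tname)}")
        sv.setDomainType(sanitize_id(tname) + "_domainType")
        sv.setSampledValue(float(geom.value_map[tname]))

    sf = g.createSampledField()
    sf.setId("sampledField")
    sf.setDataType("uint8")
    sf.setNumSamples1(nx_)
    sf.setNumSamples2(ny_)
    sf.setNumSamples3(nz_)
    sf.setInterpolationType("nearestNeighbor")
    sf.setCompression("uncompressed")
    flat = geom.grid.transpose(2, 1, 0).ravel()  # x fastest, then y, then z
    sf.setSamples(" ".join(str(int(v)) for v in flat))
    sf.setSamplesLength(flat.size)

    for sp in model.species:
        s = m.createSpecies()
        s.setId(sanitize_id(sp.id))
        s.setCompartment(sp.compartment)
        s.setInitialConcentration(sp.initial_concentration)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        s.getPlugin("spatial").setIsSpatial(True)

    for pa in model.parameters:
        p = m.createParameter()
        p.setId(sanitize_id(pa.id))
        p.setValue(pa.value)
        p.setConstant(True)
        pplug = p.getPlugin("spatial")
        if pa.role == "diffusion":
            dc = pplug.createDiffusionCoefficient()
            dc.setVariable(sanitize_id(pa.species))
            if pa.axis is None:
                dc.setType("isotropic")
            else:
                dc.setType("anisotropic")
                dc.setCoordinateReference1(_COORD_KIND[pa.axis])
        elif pa.role == "advection":
            av = pplug.createAdvectionCoefficient()
            av.setVariable(sanitize_id(pa.species))
            av.setCoordinate(_COORD_KIND[pa.axis])
        elif pa.role == "boundary-condition":
            bc = pplug.createBoundaryCondition()
            bc.setVariable(sanitize_id(pa.species))
            bc.setType("Dirichlet")
            bc.setCoordinateBoundary(pa.boundary)

    for rx in model.reactions:
        r = m.createReaction()
        r.setId(sanitize_id(rx.id))
        r.setReversible(False)
        r.setFast(False)
        if rx.compartment is not None:
            r.setCompartment(rx.compartment)
        for sp in rx.reactants:
            sr = r.createReactant()
            sr.setSpecies(sanitize_id(sp))
            sr.setStoichiometry(1.0)
            sr.setConstant(True)
        for sp in rx.products:
            sr = r.createProduct()
            sr.setSpecies(sanitize_id(sp))
            sr.setStoichiometry(1.0)
            sr.setConstant(True)
        kl = r.createKineticLaw()
        kl.setMath(libsbml.parseL3Formula(rx.rate_expression))
        r.getPlugin("spatial").setIsLocal(rx.membrane_local)

    return doc


def export_sbml(model: SpatialModel, path, force: bool = False) -> Path:
    """Validate and write the model as spatial SBML L3V1.

    Error-severity validation issues refuse the export unless ``force`` is
    set; warnings (e.g. biologically suspicious adjacency) never block.
    """
    from .validation import validate_spatial, validate_syntax

    if not force:
        issues = [
            i for i in (*validate_syntax(model), *validate_spatial(model))
            if i.severity == "error"
        ]
        if issues:
            raise ExportRefusedError(issues)
    path = Path(path)
    doc = to_document(model)
    libsbml.writeSBMLToFile(doc, str(path))
    return path


# -- import ---------------------------------------------------------------


def _read_document(path) -> libsbml.SBMLDocument:
    path = Path(path)
    if not path.exists():
        raise SBMLImportError(f"no such file: {path}")
    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_FATAL) or doc.getModel() is None:
        msgs = [
            doc.getError(i).getMessage().strip()
            for i in range(doc.getNumErrors())
        ]
        raise SBMLImportError(f"cannot parse {path}: " + "; ".join(msgs[:3]))
    return doc


def import_sbml(path) -> SpatialModel:
    """Reconstruct a :class:`SpatialModel` from a spatial SBML L3V1 file.

    Only Level 3 Version 1 documents carrying the Spatial Processes package
    are accepted; the geometry grid is decoded from the (uncompressed) sampled
    field.

    Raises
    ------
    SBMLImportError
        Wrong level/version, missing spatial package, malformed XML, or an
        undecodable sampled field.
    """
    doc = _read_document(path)
    if (doc.getLevel(), doc.getVersion()) != (3, 1):
        raise SBMLImportError(
            f"unsupported SBML Level {doc.getLevel()} Version {doc.getVersion()}; "
            "only Level 3 Version 1 is handled"
        )
    m = doc.getModel()
    mplug = m.getPlugin("spatial")
    if mplug is None or not mplug.isSetGeometry():
        raise SBMLImportError(
            "document does not use the Spatial Processes package; only spatial "
            "models can be edited"
        )
    g = mplug.getGeometry()

    # sampled field -> grid
    sfg = None
    for i in range(g.getNumGeometryDefinitions()):
        gd = g.getGeometryDefinition(i)
        if gd.getTypeCode() == libsbml.SBML_SPATIAL_SAMPLEDFIELDGEOMETRY:
            sfg = gd
            break
    if sfg is None:
        raise SBMLImportError("no sampledFieldGeometry in document")
    sf = g.getSampledField(sfg.getSampledField())
    if sf is None:
        raise SBMLImportError(f"sampled field {sfg.getSampledField()!r} not found")
    if sf.getCompression() == libsbml.SPATIAL_COMPRESSIONKIND_DEFLATED:
        raise SBMLImportError(
            "deflated sampled fields are not supported; re-export uncompressed"
        )
    nx_, ny_, nz_ = sf.getNumSamples1(), sf.getNumSamples2(), max(1, sf.getNumSamples3())
    try:
        flat = np.array([int(float(tok)) for tok in sf.getSamples().split()], dtype=np.int64)
    except ValueError as exc:
        raise SBMLImportError(f"sampled field is not trivially decodable: {exc}") from exc
    if flat.size != nx_ * ny_ * nz_:
        raise SBMLImportError(
            f"sampled field has {flat.size} samples, expected {nx_ * ny_ * nz_}"
        )
    grid = flat.reshape(nz_, ny_, nx_).transpose(2, 1, 0).astype(np.uint8)

    # domain types / sampled values
    dt_dim = {
        g.getDomainType(i).getId(): g.getDomainType(i).getSpatialDimensions()
        for i in range(g.getNumDomainTypes())
    }
    strip = lambda dtid: dtid[: -len("_domainType")] if dtid.endswith("_domainType") else dtid
    value_map: dict[str, int] = {}
    for i in range(sfg.getNumSampledVolumes()):
        sv = sfg.getSampledVolume(i)
        value_map[strip(sv.getDomainType())] = int(sv.getSampledValue())
    depth_order = sorted(value_map, key=lambda t: value_map[t])

    # spacing from coordinate bounds
    spacing = [1.0, 1.0, 1.0]
    extents = (nx_, ny_, nz_)
    for i in range(g.getNumCoordinateComponents()):
        cc = g.getCoordinateComponent(i)
        axis = {
            libsbml.SPATIAL_COORDINATEKIND_CARTESIAN_X: 0,
            libsbml.SPATIAL_COORDINATEKIND_CARTESIAN_Y: 1,
            libsbml.SPATIAL_COORDINATEKIND_CARTESIAN_Z: 2,
        }.get(cc.getType())
        if axis is None:
            continue
        width = cc.getBoundaryMax().getValue() - cc.getBoundaryMin().getValue()
        if width > 0 and extents[axis] > 0:
            spacing[axis] = width / extents[axis]

    geom = LabeledGeometry(
        grid=grid, value_map=value_map, spacing=tuple(spacing), depth_order=depth_order
    )

    # volume domains: read ids/interior points from the document; voxel counts
    # recovered by relabelling the grid (identical labelling rules → identical
    # counts for documents this package wrote)
    relabeled = {d.id: d for d in label_domains(geom)}
    mem_type_names = {strip(t) for t, dim in dt_dim.items() if dim == 2}
    volume_domains: list[Domain] = []
    membranes: list[Membrane] = []
    doc_domains = {}
    for i in range(g.getNumDomains()):
        dom = g.getDomain(i)
        tname = strip(dom.getDomainType())
        doc_domains[dom.getId()] = tname
        if tname in mem_type_names:
            continue
        ref = relabeled.get(dom.getId())
        if ref is not None:
            volume_domains.append(ref)
        else:
            ipt = (0, 0, 0)
            if dom.getNumInteriorPoints():
                p = dom.getInteriorPoint(0)
                ipt = tuple(
                    int(c / s - 0.5)
                    for c, s in zip((p.getCoord1(), p.getCoord2(), p.getCoord3()), spacing)
                )
            volume_domains.append(
                Domain(
                    id=dom.getId(),
                    domain_type=tname,
                    voxel_count=int((grid == value_map.get(tname, -1)).sum()),
                    interior_point=ipt,  # type: ignore[arg-type]
                )
            )

    # adjacency graph + membranes from adjacentDomains records
    graph = nx.Graph()
    for d in volume_domains:
        graph.add_node(d.id, domain_type=d.domain_type)
    mem_partners: dict[str, list[str]] = {}
    for i in range(g.getNumAdjacentDomains()):
        ad = g.getAdjacentDomains(i)
        d1, d2 = ad.getDomain1(), ad.getDomain2()
        mem, vol = (d1, d2) if doc_domains.get(d1) in mem_type_names else (d2, d1)
        mem_partners.setdefault(mem, []).append(vol)
    pos = {t: i for i, t in enumerate(depth_order)}
    membrane_types: dict[str, tuple[str, str]] = {}
    for mem_id in sorted(mem_partners):
        partners = mem_partners[mem_id]
        if len(partners) != 2:
            continue
        a, b = partners
        ta, tb = doc_domains.get(a, ""), doc_domains.get(b, "")
        if (pos.get(ta, -1), a) >= (pos.get(tb, -1), b):
            inner, outer, t_in, t_out = a, b, ta, tb
        else:
            inner, outer, t_in, t_out = b, a, tb, ta
        mtype = doc_domains.get(mem_id, "membrane")
        membrane_types.setdefault(mtype, (t_in, t_out))
        membranes.append(Membrane(id=mem_id, domain_type=mtype, inner=inner, outer=outer))
        if graph.has_node(inner) and graph.has_node(outer):
            graph.add_edge(inner, outer, faces=0)
    adj = AdjacencyGraph(graph=graph, membranes=membranes, membrane_types=membrane_types)

    model = SpatialModel(
        geometry=geom,
        domains=volume_domains,
        graph=adj,
        name=m.getId() or "imported_model",
    )

    for i in range(m.getNumSpecies()):
        s = m.getSpecies(i)
        model.species.append(
            Species(
                id=s.getId(),
                compartment=s.getCompartment(),
                initial_concentration=s.getInitialConcentration()
                if s.isSetInitialConcentration()
                else 0.0,
            )
        )
    axis_of = {v: k for k, v in _COORD_KIND.items()}
    for i in range(m.getNumParameters()):
        p = m.getParameter(i)
        pplug = p.getPlugin("spatial")
        role: SpatialRole = "none"
        species = axis = boundary = None
        if pplug is not None:
            if pplug.isSetDiffusionCoefficient():
                dc = pplug.getDiffusionCoefficient()
                role, species = "diffusion", dc.getVariable()
                if dc.isSetCoordinateReference1():
                    axis = axis_of.get(dc.getCoordinateReference1())
            elif pplug.isSetAdvectionCoefficient():
                av = pplug.getAdvectionCoefficient()
                role, species = "advection", av.getVariable()
                axis = axis_of.get(av.getCoordinate())
            elif pplug.isSetBoundaryCondition():
                bc = pplug.getBoundaryCondition()
                role, species = "boundary-condition", bc.getVariable()
                boundary = bc.getCoordinateBoundary() or None
        model.parameters.append(
            SpatialParameter(
                id=p.getId(), value=p.getValue(), role=role,
                species=species, axis=axis, boundary=boundary,
            )
        )
    for i in range(m.getNumReactions()):
        r = m.getReaction(i)
        rplug = r.getPlugin("spatial")
        math = r.getKineticLaw().getMath() if r.isSetKineticLaw() else None
        model.reactions.append(
            Reaction(
                id=r.getId(),
                reactants=tuple(r.getReactant(j).getSpecies() for j in range(r.getNumReactants())),
                products=tuple(r.getProduct(j).getSpecies() for j in range(r.getNumProducts())),
                rate_expression=libsbml.formulaToL3String(math) if math is not None else "0",
                membrane_local=bool(rplug.getIsLocal()) if rplug is not None else False,
                compartment=r.getCompartment() if r.isSetCompartment() else None,
            )
        )
    return model
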