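"""Model building, editing, and SBML (spatial package) round trips."""

import numpy as np
import pytest

from voxsbml import (
    LabeledGeometry,
    add_reaction,
    add_spatial_parameter,
    add_species,
    build_model,
    detect_adjacency,
    create_membranes,
    export_sbml,
    fixtures,
    import_sbml,
    label_domains,
    masks_to_model,
)
from voxsbml.errors import ExportRefusedError, InputError, SBMLImportError
from voxsbml.sbml_spatial import sanitize_id, to_document


@pytest.fixture()
def model():
    return masks_to_model(fixtures.nested_spheres(), name="nested").model


class TestBuildModel:
    def test_nested_model_has_five_domain_types(self, model):
        assert model.volume_types == ["EC", "Cyt", "Nuc"]
        assert model.membrane_types == ["NM", "PM"]
        assert len(model.domain_types) == 5
        assert model.geometry.value_map == {"EC": 0, "Cyt": 85, "Nuc": 170}

    def test_ec_only_geometry(self):
        geom = LabeledGeometry(
            grid=np.zeros((3, 3, 3), dtype=np.uint8), value_map={"EC": 0}, depth_order=["EC"]
        )
        domains = label_domains(geom)
        graph = create_membranes(detect_adjacency(geom, domains), geom.depth_order)
        m = build_model(geom, domains, graph)
        assert m.domain_types == ["EC"]
        assert len(m.domains) == 1
        assert m.graph.membranes == []

    def test_unknown_domain_type_rejected(self, model):
        from voxsbml.geometry_builder import Domain

        bad = model.domains + [Domain("X0", "X", 1, (0, 0, 0))]
        with pytest.raises(InputError, match="unknown domain type"):
            build_model(model.geometry, bad, model.graph)


class TestDocumentStructure:
    def test_level_version_and_spatial_required(self, model, tmp_path):
        path = export_sbml(model, tmp_path / "m.xml")
        text = path.read_text()
        import libsbml

        doc = libsbml.readSBML(str(path))
        assert (doc.getLevel(), doc.getVersion()) == (3, 1)
        assert doc.getPackageRequired("spatial") is True
        assert "spatial" in text

    def test_independent_xml_parse_counts_constructs(self, model, tmp_path):
        from lxml import etree

        path = export_sbml(model, tmp_path / "m.xml")
        tree = etree.parse(str(path))
        ns = {"s": "http://www.sbml.org/sbml/level3/version1/spatial/version1"}
        assert len(tree.findall(".//s:domainType", ns)) == 5
        assert len(tree.findall(".//s:domain", ns)) == 5  # EC0 Cyt0 Nuc0 PM0 NM0
        assert len(tree.findall(".//s:sampledVolume", ns)) == 3  # volumes only
        assert len(tree.findall(".//s:adjacentDomains", ns)) == 4  # 2 per membrane
        spatial_ns = "{http://www.sbml.org/sbml/level3/version1/spatial/version1}"
        values = sorted(
            float(sv.get(f"{spatial_ns}sampledValue") or sv.get("sampledValue"))
            for sv in tree.findall(".//s:sampledVolume", ns)
        )
        assert values == [0.0, 85.0, 170.0]

    def test_sampled_field_serialization_hand_computed(self, tmp_path):
        grid = np.array([[0, 85], [0, 85]], dtype=np.uint8).reshape(2, 2, 1)
        # grid[x, y, 0]: row x=0 -> (0, 85), x=1 -> (0, 85)
        geom = LabeledGeometry(
            grid=grid, value_map={"EC": 0, "Cyt": 85}, spacing=(2.0, 2.0, 2.0),
            depth_order=["EC", "Cyt"],
        )
        domains = label_domains(geom)
        graph = create_membranes(detect_adjacency(geom, domains), geom.depth_order)
        m = build_model(geom, domains, graph)
        doc = to_document(m)
        g = doc.getModel().getPlugin("spatial").getGeometry()
        sf = g.getSampledField(0)
        # x fastest: (x0,y0) (x1,y0) (x0,y1) (x1,y1) -> 0 0 85 85
        assert sf.getSamples() == "0 0 85 85"
        cc = g.getCoordinateComponent(0)
        assert cc.getBoundaryMin().getValue() == 0.0
        assert cc.getBoundaryMax().getValue() == 4.0  # 2 voxels * 2.0

    def test_interior_points_in_physical_coordinates(self, tmp_path):
        masks = fixtures.nested_spheres(spacing=(0.5, 0.5, 2.0))
        m = masks_to_model(masks, interpolate=False).model
        doc = to_document(m)
        g = doc.getModel().getPlugin("spatial").getGeometry()
        by_id = {g.getDomain(i).getId(): g.getDomain(i) for i in range(g.getNumDomains())}
        nuc = next(d for d in m.domains if d.id == "Nuc0")
        ip = by_id["Nuc0"].getInteriorPoint(0)
        x, y, z = nuc.interior_point
        assert ip.getCoord1() == pytest.approx((x + 0.5) * 0.5)
        assert ip.getCoord3() == pytest.approx((z + 0.5) * 2.0)

    def test_compartment_sizes_are_physical_volumes(self, model):
        doc = to_document(model)
        sbml_model = doc.getModel()
        voxvol = float(np.prod(model.geometry.spacing))
        for d in model.domains:
            comp = sbml_model.getCompartment(model.compartment_of(d.domain_type))
            total = sum(
                dd.voxel_count for dd in model.domains if dd.domain_type == d.domain_type
            )
            assert comp.getSize() == pytest.approx(total * voxvol)
            assert comp.getSpatialDimensions() == 3
        for t in model.membrane_types:
            assert sbml_model.getCompartment(t).getSpatialDimensions() == 2


class TestEditing:
    def test_add_species_and_duplicate_rejected(self, model):
        add_species(model, "A", "Cyt", 1.0)
        assert [s.id for s in model.species] == ["A"]
        with pytest.raises(InputError, match="duplicate"):
            add_species(model, "A", "Cyt", 2.0)

    def test_add_species_unknown_compartment(self, model):
        with pytest.raises(InputError, match="unknown compartment"):
            add_species(model, "B", "Golgi", 1.0)

    def test_membrane_species_allowed(self, model):
        add_species(model, "rec", "PM", 0.5)
        assert model.species[-1].compartment == "PM"

    def test_parameter_roles(self, model):
        add_species(model, "A", "Cyt", 1.0)
        add_spatial_parameter(model, "D_A", 1e-12, role="diffusion", species="A")
        add_spatial_parameter(model, "v_A", 0.1, role="advection", species="A", axis="x")
        add_spatial_parameter(model, "bc_A", 0.0, role="boundary-condition",
                              species="A", boundary="Xmax")
        add_spatial_parameter(model, "k1", 0.5)
        roles = {p.id: p.role for p in model.parameters}
        assert roles == {
            "D_A": "diffusion", "v_A": "advection",
            "bc_A": "boundary-condition", "k1": "none",
        }

    def test_advection_requires_axis(self, model):
        add_species(model, "A", "Cyt", 1.0)
        with pytest.raises(InputError, match="axis"):
            add_spatial_parameter(model, "v_A", 0.1, role="advection", species="A")

    def test_spatial_parameter_unknown_species(self, model):
        with pytest.raises(InputError, match="unknown species"):
            add_spatial_parameter(model, "D_X", 1.0, role="diffusion", species="X")

    def test_transport_reaction_like_published_demo(self, model):
        # simple transport of a molecule from Cyt to EC across the PM
        add_species(model, "A_cyt", "Cyt", 1.0)
        add_species(model, "A_ec", "EC", 0.0)
        add_spatial_parameter(model, "k1", 0.3)
        add_reaction(model, "transport", ["A_cyt"], ["A_ec"], "k1*A_cyt",
                     membrane_local=True, compartment="PM")
        rx = model.reactions[0]
        assert rx.membrane_local and rx.compartment == "PM"

    def test_degradation_reaction(self, model):
        add_species(model, "A", "Cyt", 1.0)
        add_spatial_parameter(model, "k1", 0.1)
        add_reaction(model, "deg", ["A"], [], "k1*A")
        assert model.reactions[0].products == ()

    def test_unknown_identifier_named_in_error(self, model):
        add_species(model, "A", "Cyt", 1.0)
        with pytest.raises(InputError, match="k9"):
            add_reaction(model, "r1", ["A"], [], "k9*A")

    def test_sanitize_id(self):
        assert sanitize_id("nuclear membrane!") == "nuclear_membrane_"
        assert sanitize_id("2nd") == "_2nd"


class TestRoundTrip:
    @pytest.mark.parametrize(
        "make_masks",
        [
            fixtures.nested_spheres,
            fixtures.multi_nucleus,
            lambda: fixtures.gapped_spheres(gap_width=2),
        ],
        ids=["nested", "multi-nucleus", "gapped"],
    )
    def test_geometry_and_lists_survive(self, make_masks, tmp_path):
        m = masks_to_model(make_masks()).model
        add_species(m, "A_cyt", "Cyt", 1.0)
        add_species(m, "A_ec", "EC", 0.0)
        add_spatial_parameter(m, "D_A", 1e-12, role="diffusion", species="A_cyt")
        add_spatial_parameter(m, "k1", 0.3)
        add_reaction(m, "transport", ["A_cyt"], ["A_ec"], "k1 * A_cyt",
                     membrane_local=True, compartment="PM")
        path = export_sbml(m, tmp_path / "rt.xml")
        back = import_sbml(path)
        assert np.array_equal(back.geometry.grid, m.geometry.grid)
        assert back.geometry.value_map == m.geometry.value_map
        assert back.geometry.spacing == pytest.approx(m.geometry.spacing)
        assert [d.id for d in back.domains] == [d.id for d in m.domains]
        assert [(d.domain_type, d.voxel_count, d.interior_point) for d in back.domains] == [
            (d.domain_type, d.voxel_count, d.interior_point) for d in m.domains
        ]
        assert back.graph.edges == m.graph.edges
        assert {(mm.id, mm.inner, mm.outer) for mm in back.graph.membranes} == {
            (mm.id, mm.inner, mm.outer) for mm in m.graph.membranes
        }
        assert back.species == m.species
        assert {p.id: (p.role, p.species) for p in back.parameters} == {
            p.id: (p.role, p.species) for p in m.parameters
        }
        assert [(r.id, r.reactants, r.products, r.membrane_local) for r in back.reactions] == [
            (r.id, r.reactants, r.products, r.membrane_local) for r in m.reactions
        ]

    def test_l2_document_rejected(self, tmp_path):
        import libsbml

        doc = libsbml.SBMLDocument(2, 4)
        doc.createModel().setId("old")
        libsbml.writeSBMLToFile(doc, str(tmp_path / "l2.xml"))
        with pytest.raises(SBMLImportError, match="Level 2 Version 4"):
            import_sbml(tmp_path / "l2.xml")

    def test_l3_without_spatial_rejected(self, tmp_path):
        import libsbml

        doc = libsbml.SBMLDocument(3, 1)
        doc.createModel().setId("plain")
        libsbml.writeSBMLToFile(doc, str(tmp_path / "plain.xml"))
        with pytest.raises(SBMLImportError, match="[Ss]patial"):
            import_sbml(tmp_path / "plain.xml")

    def test_malformed_xml_rejected(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml><model>")
        with pytest.raises(SBMLImportError, match="parse"):
            import_sbml(bad)


class TestExportGuards:
    def test_corrupted_model_refused_without_force(self, model, tmp_path):
        from voxsbml import Species

        model.species.append(
            Species(id="ghost", compartment="Golgi", initial_concentration=1.0)
        )
        with pytest.raises(ExportRefusedError, match="Golgi"):
            export_sbml(model, tmp_path / "x.xml")
        export_sbml(model, tmp_path / "x.xml", force=True)  # force overrides
        assert (tmp_path / "x.xml").exists()

    def test_fresh_document_parses_without_errors(self, model, tmp_path):
        import libsbml

        path = export_sbml(model, tmp_path / "clean.xml")
        doc = libsbml.readSBML(str(path))
        assert doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) == 0
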