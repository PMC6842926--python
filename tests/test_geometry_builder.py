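"""Containment hierarchy, grayscale merging, domain labelling, interior points."""

import numpy as np
import pytest

from oracles import flood_fill_components, interior_point_oracle
from voxsbml import (
    FOREGROUND,
    ImageStack,
    LabeledGeometry,
    containment_depths,
    containment_hierarchy,
    fixtures,
    interior_point,
    label_domains,
    merge_masks,
    resolve_overlap,
)
from voxsbml.errors import CapacityError, HierarchyError, InputError


def binary(arr, name=""):
    return ImageStack(voxels=np.where(arr, FOREGROUND, 0).astype(np.uint8), name=name)


def geom_from_grid(grid, value_map=None):
    grid = np.asarray(grid, dtype=np.uint8)
    if value_map is None:
        values = sorted(int(v) for v in np.unique(grid))
        value_map = {("EC" if v == 0 else f"T{v}"): v for v in values}
        if 0 not in values:
            value_map["EC"] = 0
    order = sorted(value_map, key=lambda t: value_map[t])
    return LabeledGeometry(grid=grid, value_map=value_map, depth_order=order)


class TestContainmentHierarchy:
    def test_nested_spheres_chain(self, nested_masks):
        assert containment_hierarchy(nested_masks) == ["EC", "Cyt", "Nuc"]

    def test_single_mask(self):
        m = fixtures.nested_spheres()["Cyt"]
        assert containment_hierarchy({"Cyt": m}) == ["EC", "Cyt"]

    def test_two_disjoint_organelles_ordered_by_size(self):
        ext = (24, 24, 24)
        cyt = fixtures._sphere(ext, (11.5, 11.5, 11.5), 10)
        big = fixtures._sphere(ext, (8.0, 11.5, 11.5), 4)
        small = fixtures._sphere(ext, (16.0, 11.5, 11.5), 2.5)
        masks = {
            "Cyt": binary(cyt, "Cyt"),
            "Mito": binary(small, "Mito"),
            "Nuc": binary(big, "Nuc"),
        }
        assert containment_hierarchy(masks) == ["EC", "Cyt", "Nuc", "Mito"]
        depths = containment_depths(masks)
        assert depths == {"EC": 0, "Cyt": 1, "Nuc": 2, "Mito": 2}

    def test_partial_overlap_is_hierarchy_error(self):
        a = np.zeros((8, 4, 4), dtype=bool)
        b = np.zeros((8, 4, 4), dtype=bool)
        a[0:5], b[3:8] = True, True
        with pytest.raises(HierarchyError, match="A.*B|B.*A"):
            containment_hierarchy({"A": binary(a, "A"), "B": binary(b, "B")})

    def test_gapped_masks_still_nest(self):
        # the cytosol shell's *footprint* (holes filled) contains the nucleus
        masks = fixtures.gapped_spheres(gap_width=2)
        assert containment_hierarchy(masks) == ["EC", "Cyt", "Nuc"]

    def test_ec_name_reserved(self):
        m = fixtures.nested_spheres()["Cyt"]
        with pytest.raises(InputError, match="reserved"):
            containment_hierarchy({"EC": m})


class TestMergeMasks:
    def test_nested_two_mask_values_are_0_85_170(self, nested_masks):
        carved = resolve_overlap(
            [nested_masks["Cyt"], nested_masks["Nuc"]], order=["Cyt", "Nuc"]
        )
        geom = merge_masks({m.name: m for m in carved}, order=["EC", "Cyt", "Nuc"])
        assert geom.value_map == {"EC": 0, "Cyt": 85, "Nuc": 170}
        assert sorted(np.unique(geom.grid).tolist()) == [0, 85, 170]

    def test_single_mask_value_127(self):
        m = fixtures.nested_spheres()["Cyt"]
        geom = merge_masks({"Cyt": m})
        assert geom.value_map == {"EC": 0, "Cyt": 127}

    def test_empty_input_gives_uniform_zero(self):
        geom = merge_masks({})
        assert geom.value_map == {"EC": 0}
        assert not geom.grid.any()

    def test_deeper_region_gets_strictly_larger_value(self):
        # five-level nesting of concentric boxes
        ext = (21, 21, 21)
        masks = {}
        for i, half in enumerate((9, 7, 5, 3, 1)):
            box = np.zeros(ext, dtype=bool)
            box[10 - half : 11 + half, 10 - half : 11 + half, 10 - half : 11 + half] = True
            masks[f"L{i}"] = binary(box, f"L{i}")
        order = containment_hierarchy(masks)
        carved = resolve_overlap([masks[n] for n in order[1:]], order=order[1:])
        geom = merge_masks({m.name: m for m in carved}, order=order)
        values = [geom.value_map[n] for n in order]
        assert values == sorted(values)
        assert len(set(values)) == len(values)
        assert values == [i * (255 // 6) for i in range(6)]

    def test_overlapping_masks_rejected(self, nested_masks):
        with pytest.raises(InputError, match="overlap"):
            merge_masks(dict(nested_masks), order=["EC", "Cyt", "Nuc"])

    def test_capacity_error_above_255_types(self):
        stacks = {
            f"T{i}": ImageStack(voxels=np.zeros((1, 1, 1), dtype=np.uint8), name=f"T{i}")
            for i in range(256)
        }
        with pytest.raises(CapacityError):
            merge_masks(stacks, order=["EC"] + list(stacks))


class TestLabelDomains:
    def test_nested_spheres_yield_three_domains(self, nested_model):
        ids = [d.id for d in nested_model.domains]
        assert ids == ["EC0", "Cyt0", "Nuc0"]

    def test_two_nuclei_get_ordinals(self):
        masks = fixtures.multi_nucleus()
        from voxsbml import masks_to_model

        model = masks_to_model(masks).model
        nuc_ids = [d.id for d in model.domains if d.domain_type == "Nuc"]
        assert nuc_ids == ["Nuc0", "Nuc1"]

    def test_partition_covers_grid(self, nested_model):
        total = sum(d.voxel_count for d in nested_model.domains)
        assert total == np.prod(nested_model.geometry.extents)

    def test_checkerboard_matches_flood_fill_count(self):
        grid = np.zeros((4, 4, 1), dtype=np.uint8)
        grid[::2, ::2, 0] = 85
        grid[1::2, 1::2, 0] = 85
        geom = geom_from_grid(grid, {"EC": 0, "Cyt": 85})
        domains = label_domains(geom)
        # 8-connected in-plane: the checkerboard's value-85 cells all touch
        labels, n = flood_fill_components(grid == 85, connectivity=26)
        n_cyt = sum(1 for d in domains if d.domain_type == "Cyt")
        assert n_cyt == n

    def test_random_grids_match_oracle(self, rng):
        from conftest import random_label_grid

        for _ in range(50):
            grid, values = random_label_grid(rng)
            vm = {("EC" if v == 0 else f"T{v}"): v for v in values}
            if 0 not in values:
                vm["EC"] = 0
            geom = geom_from_grid(grid, vm)
            domains = label_domains(geom)
            for t, v in vm.items():
                _, n = flood_fill_components(grid == v, connectivity=26)
                got = sum(1 for d in domains if d.domain_type == t)
                assert got == n, f"type {t} value {v}: {got} != oracle {n}"

    def test_translation_equivariance(self, nested_masks):
        from voxsbml import masks_to_model

        def shift(stack, delta):
            rolled = np.roll(stack.voxels, delta, axis=(0, 1, 2))
            return stack.copy_with(voxels=rolled)

        delta = (3, -2, 1)
        base = masks_to_model(nested_masks).model
        shifted = masks_to_model(
            {n: shift(m, delta) for n, m in nested_masks.items()}
        ).model
        for d0, d1 in zip(base.domains, shifted.domains):
            assert d0.id == d1.id and d0.voxel_count == d1.voxel_count
            if d0.domain_type != "EC":  # EC wraps around the border under roll
                expected = tuple(
                    (c + dl) % e
                    for c, dl, e in zip(d0.interior_point, delta, base.geometry.extents)
                )
                assert d1.interior_point == expected


class TestInteriorPoint:
    def test_cube_center(self):
        grid = np.zeros((5, 5, 5), dtype=np.uint8)
        grid[1:4, 1:4, 1:4] = 85
        geom = geom_from_grid(grid, {"EC": 0, "Cyt": 85})
        (cyt,) = [d for d in label_domains(geom) if d.domain_type == "Cyt"]
        assert interior_point(geom, cyt) == (2, 2, 2)

    def test_single_voxel_domain(self):
        grid = np.zeros((3, 3, 3), dtype=np.uint8)
        grid[1, 2, 0] = 85
        geom = geom_from_grid(grid, {"EC": 0, "Cyt": 85})
        (cyt,) = [d for d in label_domains(geom) if d.domain_type == "Cyt"]
        assert interior_point(geom, cyt) == (1, 2, 0)

    def test_shell_matches_exhaustive_oracle(self):
        grid = np.zeros((7, 7, 7), dtype=np.uint8)
        grid[1:6, 1:6, 1:6] = 85
        grid[2:5, 2:5, 2:5] = 0  # hollow the box: 1-voxel-thick shell
        geom = geom_from_grid(grid, {"EC": 0, "Cyt": 85})
        (cyt,) = [d for d in label_domains(geom) if d.domain_type == "Cyt"]
        expected = interior_point_oracle(grid, grid == 85, 85)
        assert interior_point(geom, cyt) == tuple(expected)
        assert grid[interior_point(geom, cyt)] == 85

    def test_random_grids_match_oracle(self, rng):
        from conftest import random_label_grid

        for _ in range(30):
            grid, values = random_label_grid(rng, max_extent=5)
            vm = {("EC" if v == 0 else f"T{v}"): v for v in values}
            if 0 not in values:
                vm["EC"] = 0
            geom = geom_from_grid(grid, vm)
            for d in label_domains(geom):
                v = vm[d.domain_type]
                x, y, z = d.interior_point
                assert grid[x, y, z] == v
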