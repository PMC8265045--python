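import numpy as np
import pytest

from anatscaffold import (
    DeformationSpec,
    Element,
    Mesh,
    Node,
    make_atria,
    make_body,
    make_colon,
    make_specimen,
)


def identity_cube(offset=(0.0, 0.0, 0.0), node_start=1, element_id=1, mesh=None,
                  field="coordinates"):
    """Unit-cube element whose coordinate field is the identity map
    (corners at the cube vertices, unit aligned first derivatives, zero
    cross terms), optionally translated."""
    mesh = mesh if mesh is not None else Mesh()
    if field not in mesh.fields:
        mesh.declare_field(field, 3)
    offset = np.asarray(offset, dtype=float)
    ids = []
    for c in range(8):
        corner = np.array([(c >> i) & 1 for i in range(3)], dtype=float)
        blk = np.zeros((3, 8))
        blk[:, 0] = corner + offset
        blk[0, 1] = 1.0  # d/dxi1 = x direction
        blk[1, 2] = 1.0
        blk[2, 4] = 1.0
        node = Node(node_start + c)
        node.set_field(field, blk)
        mesh.add_node(node)
        ids.append(node.id)
    mesh.add_element(Element(element_id, 3, tuple(ids)))
    return mesh


def two_shared_cubes():
    """Two unit cubes stacked along x sharing a face (conformal, C1)."""
    mesh = identity_cube()
    # second cube shares the x=1 face nodes (local corners with c1=0)
    shared = [mesh.elements[1].nodes[c] for c in range(8) if (c >> 0) & 1]
    new_ids = []
    k = 0
    corners = []
    next_id = 9
    for c in range(8):
        if (c >> 0) & 1 == 0:
            corners.append(shared[k])
            k += 1
        else:
            corner = np.array([1.0 + 1.0, (c >> 1) & 1, (c >> 2) & 1])
            corner[0] = 2.0
            blk = np.zeros((3, 8))
            blk[:, 0] = (2.0, float((c >> 1) & 1), float((c >> 2) & 1))
            blk[0, 1] = 1.0
            blk[1, 2] = 1.0
            blk[2, 4] = 1.0
            node = Node(next_id)
            node.set_field("coordinates", blk)
            mesh.add_node(node)
            corners.append(next_id)
            next_id += 1
    mesh.add_element(Element(2, 3, tuple(corners)))
    return mesh


def flat_square_2d():
    """A single 2D unit-square element in the z = 0 plane."""
    mesh = Mesh()
    mesh.declare_field("coordinates", 3)
    for c in range(4):
        blk = np.zeros((3, 8))
        blk[:, 0] = (float(c & 1), float((c >> 1) & 1), 0.0)
        blk[0, 1] = 1.0
        blk[1, 2] = 1.0
        node = Node(1 + c)
        node.set_field("coordinates", blk)
        mesh.add_node(node)
    mesh.add_element(Element(1, 2, (1, 2, 3, 4)))
    return mesh


def curved_square_2d(amplitude=0.3):
    """A 2D element bulging out of the z = 0 plane (nonzero z derivatives)."""
    mesh = flat_square_2d()
    for c, node in enumerate(mesh.nodes.values()):
        blk = node.params["coordinates"][0]
        # saddle-ish z values and slopes
        u, v = float(c & 1), float((c >> 1) & 1)
        blk[2, 0] = amplitude * (u - 0.5) * (v - 0.5)
        blk[2, 1] = amplitude * (v - 0.5)
        blk[2, 2] = amplitude * (u - 0.5)
    return mesh


@pytest.fixture(scope="session")
def mouse_colon():
    return make_colon("mouse-colon")


@pytest.fixture(scope="session")
def human_colon():
    return make_colon("human-colon")


@pytest.fixture(scope="session")
def rat_atria():
    return make_atria(preset="rat-atria")


@pytest.fixture(scope="session")
def rat_body():
    return make_body()


@pytest.fixture(scope="session")
def atria_specimen(rat_atria):
    """Rat-atria synthetic specimen: 10% bend, noise-free contours, 40 cells."""
    spec = DeformationSpec(mode="bend", amplitude=0.10, noise_sd=0.0, seed=1)
    return make_specimen(rat_atria, spec, n_cells=40,
                         rings_per_element=2, points_per_ring=6)
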