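import numpy as np
import pytest

from atriumfsi.geometry import build_idealized_la
from atriumfsi.fibres import partition_sections, assign_fibres
from atriumfsi.scenarios import ScenarioConfig, run_case
from atriumfsi.fe import StructureMesh


@pytest.fixture(scope="session")
def la_mesh():
    """Default Table-calibrated idealized LA mesh (built once)."""
    return build_idealized_la()


@pytest.fixture(scope="session")
def la_sections(la_mesh):
    return partition_sections(la_mesh)


@pytest.fixture(scope="session")
def la_fibres(la_mesh, la_sections):
    return assign_fibres(la_mesh, la_sections)


@pytest.fixture(scope="session")
def case_results():
    """Lazily run and cache the coupled scenario cases (expensive)."""
    cache = {}

    def get(case):
        if case not in cache:
            cfg = ScenarioConfig.from_case(case)
            if case == "original":
                # a third cycle for the cycle-2 vs cycle-3 periodicity check
                from dataclasses import replace
                cfg = replace(cfg, n_cycles=3)
            cache[case] = run_case(cfg)
        return cache[case]

    return get


def hex_block(nx=2, ny=2, nz=2, lx=1.0, ly=1.0, lz=1.0, fibre=(1.0, 0.0, 0.0)):
    """Structured trilinear-hex block on [0,lx]x[0,ly]x[0,lz]."""
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    conn = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                conn.append([nid(i, j, k), nid(i + 1, j, k),
                             nid(i + 1, j + 1, k), nid(i, j + 1, k),
                             nid(i, j, k + 1), nid(i + 1, j, k + 1),
                             nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
    conn = np.asarray(conn)
    fib = np.tile(np.asarray(fibre, float), (len(conn), 1))
    return StructureMesh(nodes=nodes, elem_type="hex8", conn=conn, fibre=fib)


def quad_block(nx=3, ny=3, lx=1.0, ly=1.0, fibre=(1.0, 0.0)):
    """Structured bilinear-quad block on [0,lx]x[0,ly]."""
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    conn = []
    for i in range(nx):
        for j in range(ny):
            conn.append([nid(i, j), nid(i + 1, j),
                         nid(i + 1, j + 1), nid(i, j + 1)])
    conn = np.asarray(conn)
    fib = np.tile(np.asarray(fibre, float), (len(conn), 1))
    return StructureMesh(nodes=nodes, elem_type="quad4", conn=conn, fibre=fib)
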