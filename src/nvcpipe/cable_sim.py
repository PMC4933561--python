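"""Passive multicompartment cable simulation under a dendritic slab clamp.

Models the question: can a step depolarization of the superficial part
of a bipolar interneuron's dendritic tree — as produced by light-gated
cation channels with ~0 mV reversal potential opening in the upper
cortical layers — depolarize a soma situated several hundred
micrometres deeper?

Pipeline:

1. ``read_swc`` parses a standard 7-column SWC morphology; z is treated
   as cortical depth (increasing downward).  ``orient_depth`` flips and
   shifts reconstructions whose z axis points the other way.
2. ``scale_z`` compresses the depth axis (rat -> mouse cortical
   thickness, factor 0.6); ``stretch_to_layer5`` affinely stretches the
   middle dendritic section (between 100 um below the surface and the
   soma) so the soma lands at 600 um depth, approximating a deep-layer
   bipolar cell while leaving the superficial tuft untouched.
3. ``discretize`` splits every neurite into cylindrical compartments of
   at most 10 um, conserving membrane area.
4. ``solve_clamped`` holds all dendritic compartments whose midpoints
   lie within the top slab at the clamp voltage and solves the passive
   cable equation for the rest: steady state as a sparse linear system,
   the transient by implicit (backward Euler) time stepping.

Membrane properties are passive throughout (no voltage-gated
conductances), so all potentials are bounded between the resting and
clamp values and the computed somatic depolarization is a lower bound
on what an active dendrite could deliver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu, spsolve

log = logging.getLogger(__name__)

SOMA, AXON, DENDRITE = 1, 2, 3
_DENDRITE_TYPES = (3, 4)    # basal + apical dendrite SWC codes


@dataclass
class Morphology:
    """SWC-style compartment tree (parallel arrays, one entry per node)."""

    ids: np.ndarray          # int, original SWC ids
    types: np.ndarray        # int structure codes (1 soma, 2 axon, 3/4 dendrite)
    xyz: np.ndarray          # (n, 3) um; z = depth below the cortical surface
    radius: np.ndarray       # um
    parent_index: np.ndarray  # index into these arrays; -1 for the root

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def soma_z(self) -> float:
        """Mean depth of the soma node(s)."""
        mask = self.types == SOMA
        if not mask.any():
            raise ValueError("morphology has no soma node")
        return float(self.z[mask].mean())

    def total_length(self, types: tuple[int, ...] | None = None) -> float:
        """Summed segment length (um), optionally restricted to node types."""
        total = 0.0
        for i in range(self.n_nodes):
            p = self.parent_index[i]
            if p < 0:
                continue
            if types is not None and self.types[i] not in types:
                continue
            total += float(np.linalg.norm(self.xyz[i] - self.xyz[p]))
        return total

    def copy(self) -> "Morphology":
        return Morphology(self.ids.copy(), self.types.copy(), self.xyz.copy(),
                          self.radius.copy(), self.parent_index.copy())


def read_swc(source: str | Path) -> Morphology:
    """Parse SWC text (path or literal content); validates the tree.

    Errors (missing parent, non-positive radius, cycle) name the
    offending line/node.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    ids, types, xyz, radius, parents = [], [], [], [], []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"SWC line {lineno}: expected 7 columns, got {len(parts)}")
        nid, stype = int(parts[0]), int(parts[1])
        x, y, z, r = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        if r <= 0:
            raise ValueError(f"SWC line {lineno}: non-positive radius for node {nid}")
        ids.append(nid); types.append(stype)
        xyz.append((x, y, z)); radius.append(r); parents.append(parent)
    if not ids:
        raise ValueError("SWC source contains no nodes")
    id_to_index = {nid: i for i, nid in enumerate(ids)}
    parent_index = np.empty(len(ids), dtype=int)
    roots = 0
    for i, p in enumerate(parents):
        if p == -1:
            parent_index[i] = -1
            roots += 1
        else:
            if p not in id_to_index:
                raise ValueError(f"node {ids[i]} references missing parent {p}")
            parent_index[i] = id_to_index[p]
            if parent_index[i] >= i:
                raise ValueError(f"node {ids[i]}: parent must precede child")
    if roots != 1:
        raise ValueError(f"morphology must have exactly one root, found {roots}")
    return Morphology(np.array(ids), np.array(types), np.array(xyz, dtype=float),
                      np.array(radius, dtype=float), parent_index)


def orient_depth(m: Morphology, tip_depth: float = 20.0) -> Morphology:
    """Express z as cortical depth with the dendritic tuft superficial.

    Reconstruction files are usually soma-centred with an arbitrary z
    sign.  If the longest dendritic excursion points toward positive z
    (downward), the tree is flipped (logged); the whole tree is then
    translated so the shallowest dendritic tip sits at ``tip_depth``.
    """
    out = m.copy()
    dmask = np.isin(out.types, _DENDRITE_TYPES)
    if not dmask.any():
        raise ValueError("morphology has no dendrites to orient")
    soma_z = out.soma_z()
    dz = out.z[dmask] - soma_z
    if abs(dz.max()) > abs(dz.min()):
        log.info("orient_depth: flipping z axis (apical excursion pointed downward)")
        out.xyz[:, 2] = -out.xyz[:, 2]
    shift = tip_depth - out.z[np.isin(out.types, _DENDRITE_TYPES)].min()
    out.xyz[:, 2] += shift
    return out


def scale_z(m: Morphology, factor: float = 0.6) -> Morphology:
    """Scale the depth axis only (x, y, radii untouched)."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    out = m.copy()
    out.xyz[:, 2] *= factor
    return out


def stretch_to_layer5(m: Morphology, fixed_above: float = 100.0,
                      soma_target_depth: float = 600.0) -> Morphology:
    """Stretch the middle section so the soma lands in layer V.

    Depths above ``fixed_above`` (the layer I/II border) are unchanged;
    depths between ``fixed_above`` and the soma are scaled affinely so
    the soma reaches ``soma_target_depth``; everything deeper than the
    soma is translated rigidly by the soma's displacement.  All neurite
    types passing through the middle section are stretched alike.
    """
    soma_z = m.soma_z()
    if soma_z <= fixed_above:
        raise ValueError("soma must lie below the fixed superficial section")
    k = (soma_target_depth - fixed_above) / (soma_z - fixed_above)
    shift = soma_target_depth - soma_z
    out = m.copy()
    z = out.xyz[:, 2]
    middle = (z > fixed_above) & (z <= soma_z)
    below = z > soma_z
    out.xyz[middle, 2] = fixed_above + (z[middle] - fixed_above) * k
    out.xyz[below, 2] = z[below] + shift
    return out


# ---------------------------------------------------------------------------
# compartmentalization
# ---------------------------------------------------------------------------

@dataclass
class CompartmentGraph:
    """Cylindrical compartments with tree connectivity.

    ``parent[i]`` is the index of compartment i's proximal neighbour
    (-1 for the soma root).  Areas are lateral cylinder areas except the
    soma, which uses its equivalent sphere surface.
    """

    length_um: np.ndarray
    radius_um: np.ndarray
    area_um2: np.ndarray
    z_um: np.ndarray           # midpoint depth
    types: np.ndarray
    parent: np.ndarray
    soma_index: int

    @property
    def n(self) -> int:
        return len(self.length_um)


def discretize(m: Morphology, max_compartment_length: float = 10.0
               ) -> CompartmentGraph:
    """Split every parent-child segment into compartments <= max length.

    Radii vary linearly along each segment, so total membrane area is
    conserved to the frustum value within 1%.  A single-node soma
    becomes one compartment with sphere surface area and an equivalent
    cylinder (length = diameter) for axial coupling.
    """
    if max_compartment_length <= 0:
        raise ValueError("max_compartment_length must be > 0")
    lengths, radii, areas, zs, types, parents = [], [], [], [], [], []

    soma_nodes = np.nonzero(m.types == SOMA)[0]
    if soma_nodes.size == 0:
        raise ValueError("morphology has no soma")
    r_soma = float(m.radius[soma_nodes].max())
    lengths.append(2.0 * r_soma)
    radii.append(r_soma)
    areas.append(4.0 * np.pi * r_soma ** 2)
    zs.append(float(m.z[soma_nodes].mean()))
    types.append(SOMA)
    parents.append(-1)
    soma_comp = 0

    node_comp = {int(i): soma_comp for i in soma_nodes}
    for i in range(m.n_nodes):
        p = int(m.parent_index[i])
        if p < 0 or m.types[i] == SOMA:
            continue
        p_comp = node_comp.get(p, soma_comp)
        a, b = m.xyz[p], m.xyz[i]
        seg_len = float(np.linalg.norm(b - a))
        if seg_len == 0:
            node_comp[i] = p_comp
            continue
        n_sub = max(1, int(np.ceil(seg_len / max_compartment_length)))
        r0 = float(m.radius[p]) if m.types[p] != SOMA else float(m.radius[i])
        r1 = float(m.radius[i])
        prev = p_comp
        for s in range(n_sub):
            frac_mid = (s + 0.5) / n_sub
            r_mid = r0 + (r1 - r0) * frac_mid
            sub_len = seg_len / n_sub
            lengths.append(sub_len)
            radii.append(r_mid)
            areas.append(2.0 * np.pi * r_mid * sub_len)
            zs.append(float(a[2] + (b[2] - a[2]) * frac_mid))
            types.append(int(m.types[i]))
            parents.append(prev)
            prev = len(lengths) - 1
        node_comp[i] = prev

    return CompartmentGraph(
        length_um=np.array(lengths), radius_um=np.array(radii),
        area_um2=np.array(areas), z_um=np.array(zs),
        types=np.array(types), parent=np.array(parents, dtype=int),
        soma_index=soma_comp)


# ---------------------------------------------------------------------------
# passive solver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane properties (textbook defaults).

    membrane_resistance in kOhm*cm^2, capacitance in uF/cm^2, axial
    resistivity in Ohm*cm, resting potential in mV.
    """

    membrane_resistance: float = 30.0
    membrane_capacitance: float = 1.0
    axial_resistivity: float = 150.0
    resting_potential: float = -70.0

    def __post_init__(self) -> None:
        if min(self.membrane_resistance, self.membrane_capacitance,
               self.axial_resistivity) <= 0:
            raise ValueError("membrane and axial parameters must be positive")


@dataclass(frozen=True)
class ClampSpec:
    """Voltage clamp of the dendritic compartments in the top slab."""

    slab_depth_um: float = 100.0
    clamp_voltage_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.slab_depth_um <= 0:
            raise ValueError("slab_depth_um must be > 0")


@dataclass
class CableSolution:
    """Steady-state and transient solution of the clamped passive tree."""

    v_steady_mV: np.ndarray      # per compartment
    soma_time_ms: np.ndarray
    soma_trace_mV: np.ndarray
    time_to_90pct_ms: float
    clamped: np.ndarray          # bool mask per compartment
    soma_index: int

    @property
    def soma_steady_mV(self) -> float:
        return float(self.v_steady_mV[self.soma_index])


def _conductances(graph: CompartmentGraph, params: PassiveParams):
    """Per-compartment membrane conductance/capacitance and axial couplings.

    Conductances in uS, capacitances in nF (so time constants come out
    in ms with voltages in mV and currents in nA).
    """
    area_cm2 = graph.area_um2 * 1e-8
    g_m = area_cm2 / (params.membrane_resistance * 1e3) * 1e6       # uS
    c_m = params.membrane_capacitance * area_cm2 * 1e3              # nF
    # axial: R = Ra * (l_i/2A_i + l_p/2A_p); lengths/areas in cm
    half_r = (params.axial_resistivity
              * (graph.length_um * 1e-4) / 2.0
              / (np.pi * (graph.radius_um * 1e-4) ** 2))            # Ohm
    edges = []
    for i in range(graph.n):
        p = graph.parent[i]
        if p < 0:
            continue
        g_ax = 1.0 / (half_r[i] + half_r[p]) * 1e6                  # uS
        edges.append((i, p, g_ax))
    return g_m, c_m, edges


def solve_clamped(graph: CompartmentGraph, params: PassiveParams,
                  clamp: ClampSpec, duration_ms: float = 200.0,
                  dt_ms: float = 0.1) -> CableSolution:
    """Clamp the superficial dendritic slab and solve the passive tree.

    Clamped compartments (dendritic, midpoint depth <= slab depth) are
    held at the clamp voltage from t = 0; all others start at rest.
    Steady state is the solution of the sparse conductance system;
    the transient uses backward Euler at ``dt_ms`` (<= 0.1 ms).
    """
    if dt_ms > 0.1:
        raise ValueError("dt_ms must be <= 0.1 ms")
    clamped = np.isin(graph.types, _DENDRITE_TYPES) & (graph.z_um <= clamp.slab_depth_um)
    if not clamped.any():
        raise ValueError("no dendritic compartment lies within the clamp slab")
    g_m, c_m, edges = _conductances(graph, params)
    n = graph.n
    free = np.nonzero(~clamped)[0]
    pos_of = -np.ones(n, dtype=int)
    pos_of[free] = np.arange(free.size)

    rows, cols, vals = [], [], []
    diag = g_m[free].astype(float).copy()
    b_const = g_m[free] * params.resting_potential
    b_clamp = np.zeros(free.size)
    for i, p, g_ax in edges:
        for a, bnode in ((i, p), (p, i)):
            if clamped[a]:
                continue
            ia = pos_of[a]
            diag[ia] += g_ax
            if clamped[bnode]:
                b_clamp[ia] += g_ax * clamp.clamp_voltage_mV
            else:
                rows.append(ia); cols.append(pos_of[bnode]); vals.append(-g_ax)
    rows.extend(range(free.size)); cols.extend(range(free.size)); vals.extend(diag)
    G = csc_matrix((vals, (rows, cols)), shape=(free.size, free.size))
    rhs = b_const + b_clamp
    v_free_ss = spsolve(G, rhs)
    v_steady = np.full(n, clamp.clamp_voltage_mV)
    v_steady[free] = v_free_ss

    # transient: (C/dt + G) v_{k+1} = C/dt v_k + rhs
    n_steps = int(round(duration_ms / dt_ms))
    Cdt = c_m[free] / dt_ms
    A = G + csc_matrix((Cdt, (range(free.size), range(free.size))),
                       shape=(free.size, free.size))
    lu = splu(A)
    v = np.full(free.size, params.resting_potential)
    soma_pos = pos_of[graph.soma_index]
    soma_trace = np.empty(n_steps + 1)
    if soma_pos < 0:    # soma inside the clamp (whole-cell clamp)
        soma_trace[:] = clamp.clamp_voltage_mV
        for _ in range(n_steps):
            v = lu.solve(Cdt * v + rhs)
    else:
        soma_trace[0] = v[soma_pos]
        for k in range(n_steps):
            v = lu.solve(Cdt * v + rhs)
            soma_trace[k + 1] = v[soma_pos]
    t = np.arange(n_steps + 1) * dt_ms

    v0, v_inf = soma_trace[0], (v_steady[graph.soma_index])
    if abs(v_inf - v0) < 1e-12:
        t90 = 0.0
    else:
        frac = (soma_trace - v0) / (v_inf - v0)
        reached = np.nonzero(frac >= 0.9)[0]
        t90 = float(t[reached[0]]) if reached.size else float("nan")
    return CableSolution(v_steady_mV=v_steady, soma_time_ms=t,
                         soma_trace_mV=soma_trace, time_to_90pct_ms=t90,
                         clamped=clamped, soma_index=graph.soma_index)


def morph_and_solve(swc_source: str | Path, clamp: ClampSpec,
                    params: PassiveParams | None = None,
                    z_scale: float = 0.6, fixed_above: float = 100.0,
                    soma_target_depth: float = 600.0,
                    max_compartment_length: float = 10.0,
                    duration_ms: float = 200.0) -> CableSolution:
    """Full chain: read -> orient -> Z-scale -> stretch -> discretize -> clamp."""
    m = orient_depth(read_swc(swc_source))
    m = scale_z(m, z_scale)
    m = stretch_to_layer5(m, fixed_above=fixed_above,
                          soma_target_depth=soma_target_depth)
    graph = discretize(m, max_compartment_length)
    return solve_clamped(graph, params or PassiveParams(), clamp,
                         duration_ms=duration_ms)
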