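"""Synthetic inputs for every analysis stage, with ground truth.

Each generator is a deterministic function of its spec (which carries the
seed) and returns the ground truth needed to score the corresponding
analysis: a toy four-helix protomer for assembly and surface geometry,
localization fields with round versus branched-filamentous clusters and
multi-localization blinking for the SMLM morphometrics, EC tables with
planted intra/inter/far pairs for the coupling classifier, and three-phase
dithionite-quench traces with a planted permeability.

The branched-cluster morphology (persistent, self-avoiding branching walks)
is a test fixture reproducing the scale and anisotropy of pyroptotic
protein clusters; it is not claimed to model the underlying biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import biotite.structure as struc
import numpy as np

from .assays import (
    AssayTrace,
    PHASE_BASELINE,
    PHASE_DITHIONITE,
    PHASE_TRITON,
    permeability_from_levels,
)
from .assembly import AssemblyModel, NINJ1_HELIX_RANGES, ProtomerModel
from .coevolution import (
    CouplingPair,
    LABEL_EXCLUDED,
    LABEL_INTER,
    LABEL_INTRA,
)
from .errors import InvalidModelError
from .smlm import LocalizationTable

_AA3 = {"L": "LEU", "K": "LYS", "E": "GLU", "A": "ALA", "G": "GLY", "F": "PHE",
        "S": "SER", "V": "VAL", "I": "ILE", "D": "ASP", "N": "ASN", "Q": "GLN"}

# ideal alpha-helix CA geometry
HELIX_RISE_PER_RES = 1.5  # A
HELIX_TWIST_PER_RES = 100.0  # degrees
HELIX_RADIUS = 2.3  # A


# ---------------------------------------------------------------------------
# toy protomer


@dataclass
class ProtomerSpec:
    """Four-helix toy protomer: ideal helices on parallel axes.

    ``helix_ranges`` follows the NINJ1 annotation by default. Helices are
    placed on axes parallel to z at ``packing_offsets`` (A in the x-y
    plane) with alternating up/down direction (helix hairpins). Residues
    with side chains pointing towards +x get Leu (the planted hydrophobic
    face); the rest alternate Lys/Glu. ``jitter_sigma`` adds seeded
    Gaussian positional noise.
    """

    first_residue: int = 39
    last_residue: int = 141
    helix_ranges: dict = field(default_factory=lambda: dict(NINJ1_HELIX_RANGES))
    packing_offsets: tuple = ((-4.0, -4.0), (4.0, -4.0), (4.0, 4.0), (-4.0, 4.0))
    jitter_sigma: float = 0.0
    seed: int = 0


def synth_protomer(spec: ProtomerSpec | None = None) -> ProtomerModel:
    """Generate a toy four-helix protomer with an engineered hydrophobic face."""
    if spec is None:
        spec = ProtomerSpec()
    rng = np.random.default_rng(spec.seed)
    n_res = spec.last_residue - spec.first_residue + 1
    res_ids = np.arange(spec.first_residue, spec.last_residue + 1)
    coords = np.full((n_res, 3), np.nan)

    ranges = sorted(spec.helix_ranges.items(), key=lambda kv: kv[1][0])
    for h, (name, (start, end)) in enumerate(ranges):
        ox, oy = spec.packing_offsets[h % len(spec.packing_offsets)]
        length = end - start + 1
        direction = 1.0 if h % 2 == 0 else -1.0
        z0 = -direction * (length - 1) * HELIX_RISE_PER_RES / 2.0
        for r in range(length):
            theta = math.radians(HELIX_TWIST_PER_RES * r)
            idx = start - spec.first_residue + r
            coords[idx] = (
                ox + HELIX_RADIUS * math.cos(theta),
                oy + HELIX_RADIUS * math.sin(theta),
                z0 + direction * HELIX_RISE_PER_RES * r,
            )

    # linear loops / termini between and around helices
    known = np.flatnonzero(~np.isnan(coords[:, 0]))
    first_k, last_k = known[0], known[-1]
    for idx in range(n_res):
        if not np.isnan(coords[idx, 0]):
            continue
        if idx < first_k:
            coords[idx] = coords[first_k] + (first_k - idx) * np.array([0.0, 0.0, -3.0])
        elif idx > last_k:
            coords[idx] = coords[last_k] + (idx - last_k) * np.array([0.0, 0.0, 3.0])
        else:
            prev_k = known[known < idx].max()
            next_k = known[known > idx].min()
            frac = (idx - prev_k) / (next_k - prev_k)
            coords[idx] = (1 - frac) * coords[prev_k] + frac * coords[next_k]

    if spec.jitter_sigma > 0:
        coords = coords + rng.normal(0.0, spec.jitter_sigma, coords.shape)

    center_xy = coords[:, :2].mean(axis=0)
    sequence = []
    polar_cycle = "KE"
    n_polar = 0
    for idx in range(n_res):
        if coords[idx, 0] - center_xy[0] > 0.5:
            sequence.append("L")
        else:
            sequence.append(polar_cycle[n_polar % 2])
            n_polar += 1
    sequence = "".join(sequence)

    atoms = struc.AtomArray(n_res)
    atoms.coord = coords
    atoms.chain_id = np.full(n_res, "A", dtype="U4")
    atoms.res_id = res_ids
    atoms.res_name = np.array([_AA3[c] for c in sequence], dtype="U3")
    atoms.atom_name = np.full(n_res, "CA", dtype="U6")
    atoms.element = np.full(n_res, "C", dtype="U2")
    atoms.hetero = np.zeros(n_res, dtype=bool)
    return ProtomerModel(atoms=atoms, sequence=sequence, helix_ranges=dict(spec.helix_ranges))


# ---------------------------------------------------------------------------
# localization fields


@dataclass
class ClusterComponentSpec:
    """One kind of planted cluster in a localization field."""

    kind: str  # "dot" | "round" | "branched_filament"
    count: int
    size_nm: float = 100.0  # extent scale of one cluster
    locs_per_site_mean: float = 3.0  # geometric blinking
    precision_nm: float = 15.0  # localization jitter sigma


@dataclass
class FieldSpec:
    """A synthetic SMLM field: planted clusters plus uniform background."""

    field_size_um: tuple = (20.0, 20.0)
    components: list = field(default_factory=list)
    background_density_um2: float = 0.5
    step_nm: float = 20.0  # walk step for branched clusters
    branch_prob: float = 0.02  # per-step branching probability
    seed: int = 0

    @property
    def area_um2(self) -> float:
        return self.field_size_um[0] * self.field_size_um[1]


def untreated_field(seed: int = 0) -> FieldSpec:
    """Field emulating a live (non-activated) cell: homogeneous small dots
    and a few small, mostly round clusters."""
    return FieldSpec(
        components=[
            ClusterComponentSpec(kind="dot", count=150, size_nm=0.0,
                                 locs_per_site_mean=2.0, precision_nm=15.0),
            ClusterComponentSpec(kind="round", count=8, size_nm=120.0,
                                 locs_per_site_mean=3.0, precision_nm=15.0),
        ],
        background_density_um2=0.3,
        seed=seed,
    )


def pyroptotic_field(seed: int = 0) -> FieldSpec:
    """Field emulating a pyroptotic cell: large, branched-filamentous
    clusters (500 nm to micrometre extents) over residual dots."""
    return FieldSpec(
        components=[
            ClusterComponentSpec(kind="dot", count=60, size_nm=0.0,
                                 locs_per_site_mean=2.0, precision_nm=15.0),
            ClusterComponentSpec(kind="branched_filament", count=12, size_nm=1000.0,
                                 locs_per_site_mean=3.0, precision_nm=15.0),
        ],
        background_density_um2=0.3,
        seed=seed,
    )


def _branched_walk(rng, origin, size_nm, step_nm, branch_prob):
    """Persistent, softly self-avoiding branching walk; returns site array."""
    n_steps = max(3, int(round(size_nm / step_nm)))
    sites = [np.asarray(origin, float)]
    # (position, direction, remaining steps) per active branch tip
    tips = [(sites[0], rng.uniform(0, 2 * math.pi), n_steps)]
    while tips:
        pos, ang, remaining = tips.pop()
        for k in range(remaining):
            ang += rng.normal(0.0, 0.3)
            for _ in range(4):  # soft self-avoidance: retry turns
                cand = pos + step_nm * np.array([math.cos(ang), math.sin(ang)])
                near = np.linalg.norm(np.asarray(sites) - cand, axis=1)
                if (near > 0.5 * step_nm).all():
                    break
                ang += rng.uniform(-1.2, 1.2)
            pos = cand
            sites.append(pos)
            if rng.uniform() < branch_prob and remaining - k > 3:
                tips.append(
                    (pos, ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.8, 1.6),
                     (remaining - k) // 2)
                )
    return np.asarray(sites)


def _component_sites(rng, comp: ClusterComponentSpec, origin, spec: FieldSpec):
    if comp.kind == "dot":
        return np.asarray(origin, float).reshape(1, 2)
    if comp.kind == "round":
        n_sites = max(8, int(round(comp.size_nm / 10.0)))
        radii = comp.size_nm / 2.0 * np.sqrt(rng.uniform(size=n_sites))
        angles = rng.uniform(0, 2 * math.pi, n_sites)
        return origin + np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    if comp.kind == "branched_filament":
        return _branched_walk(rng, origin, comp.size_nm, spec.step_nm, spec.branch_prob)
    raise InvalidModelError(f"unknown cluster kind {comp.kind!r}")


def synth_localizations(spec: FieldSpec) -> tuple[LocalizationTable, np.ndarray]:
    """Generate a localization field; returns the table and ground-truth ids.

    Ground truth is one integer per localization: the planted component
    index, or -1 for uniform background. Blinking draws a geometric number
    of localizations per fluorophore site (mean ``locs_per_site_mean``),
    each displaced by Gaussian noise of the localization precision.
    """
    rng = np.random.default_rng(spec.seed)
    w_nm = spec.field_size_um[0] * 1000.0
    h_nm = spec.field_size_um[1] * 1000.0
    xs, ys, truth = [], [], []

    component_id = 0
    for comp in spec.components:
        for _ in range(comp.count):
            margin = min(comp.size_nm + 100.0, min(w_nm, h_nm) / 4)
            origin = rng.uniform([margin, margin], [w_nm - margin, h_nm - margin])
            sites = _component_sites(rng, comp, origin, spec)
            for site in sites:
                n_loc = rng.geometric(1.0 / max(comp.locs_per_site_mean, 1.0))
                pts = site + rng.normal(0.0, comp.precision_nm, (n_loc, 2))
                xs.append(pts[:, 0])
                ys.append(pts[:, 1])
                truth.append(np.full(n_loc, component_id))
            component_id += 1

    n_bg = rng.poisson(spec.background_density_um2 * spec.area_um2)
    if n_bg:
        xs.append(rng.uniform(0, w_nm, n_bg))
        ys.append(rng.uniform(0, h_nm, n_bg))
        truth.append(np.full(n_bg, -1))

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        truth = np.concatenate(truth).astype(int)
    else:
        x = y = np.empty(0)
        truth = np.empty(0, dtype=int)
    frames = rng.integers(0, 10_000, len(x))
    table = LocalizationTable.from_xy(
        np.column_stack([x, y]) if len(x) else np.empty((0, 2)),
        frame=frames,
        field_area_um2=spec.area_um2,
    )
    return table, truth


# ---------------------------------------------------------------------------
# EC tables with planted labels


def _ca_stack(assembly: AssemblyModel) -> tuple[np.ndarray, np.ndarray]:
    """(S, R, 3) CA coordinates and the residue ids (shared across subunits)."""
    res_ids = None
    stacks = []
    for s in range(assembly.n_subunits):
        sl = assembly._slice(s)
        sub = assembly.atoms[sl]
        mask = sub.atom_name == "CA"
        ids = sub.res_id[mask]
        if res_ids is None:
            res_ids = ids
        stacks.append(assembly.coords[sl][mask])
    return np.stack(stacks), res_ids


def synth_ec_table(
    assembly: AssemblyModel,
    n_intra: int = 20,
    n_inter: int = 9,
    n_far: int = 10,
    score_range: tuple = (0.55, 0.95),
    seed: int = 0,
) -> tuple[list, dict]:
    """Plant EC pairs with known intra/inter/excluded ground truth.

    Scans all residue pairs of the assembly, bins them by the classifier's
    own geometric criterion evaluated on exact coordinates (inter: cross-
    subunit distance shorter than intra and within 12 A; intra: the
    reverse; far: both above 12 A) and samples the requested number from
    each bin with scores uniform in ``score_range``. Returns the pair list
    and a dict mapping (res_i, res_j) to the planted label.
    """
    if assembly.n_subunits < 2:
        raise InvalidModelError("EC planting needs an assembly with >= 2 subunits")
    rng = np.random.default_rng(seed)
    ca, res_ids = _ca_stack(assembly)
    S, R, _ = ca.shape
    d_intra = np.linalg.norm(ca[0][:, None, :] - ca[0][None, :, :], axis=-1)
    d_inter = np.full((R, R), np.inf)
    for p in range(S):
        for q in range(S):
            if p == q:
                continue
            d = np.linalg.norm(ca[p][:, None, :] - ca[q][None, :, :], axis=-1)
            d_inter = np.minimum(d_inter, d)

    iu = np.triu_indices(R, k=1)
    cats = {LABEL_INTRA: [], LABEL_INTER: [], LABEL_EXCLUDED: []}
    for a, b in zip(*iu):
        di, de = d_intra[a, b], d_inter[a, b]
        if min(di, de) > 12.0:
            cats[LABEL_EXCLUDED].append((a, b))
        elif de < di:
            cats[LABEL_INTER].append((a, b))
        elif di < de:
            cats[LABEL_INTRA].append((a, b))

    wanted = {LABEL_INTRA: n_intra, LABEL_INTER: n_inter, LABEL_EXCLUDED: n_far}
    pairs, truth = [], {}
    for label, n in wanted.items():
        pool = cats[label]
        if n > len(pool):
            raise InvalidModelError(
                f"cannot plant {n} {label} pairs; only {len(pool)} candidates exist"
            )
        for k in rng.choice(len(pool), size=n, replace=False):
            a, b = pool[int(k)]
            ri, rj = int(res_ids[a]), int(res_ids[b])
            score = float(rng.uniform(*score_range))
            pairs.append(CouplingPair(res_i=ri, res_j=rj, score=score))
            truth[(ri, rj)] = label
    order = rng.permutation(len(pairs))
    return [pairs[int(i)] for i in order], truth


# ---------------------------------------------------------------------------
# dithionite-quench traces


@dataclass
class TraceSpec:
    """Three-phase dithionite-quench trace following the assay protocol:
    180 s baseline, dithionite quench recorded for 500 s until plateau,
    then Triton X-100 for 60 s."""

    f_initial: float = 1.0
    f_dit: float = 0.5
    f_triton: float = 0.02
    durations_s: tuple = (180.0, 500.0, 60.0)
    tau_dit_s: float = 30.0
    tau_triton_s: float = 5.0
    noise_sigma: float = 0.0  # Gaussian noise, fraction of f_initial
    dt_s: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.durations_s):
            raise InvalidModelError("phase durations must be positive")


def synth_trace(spec: TraceSpec) -> tuple[AssayTrace, float]:
    """Generate a three-phase quench trace; returns it with the planted
    (noiseless) permeability implied by the phase levels."""
    rng = np.random.default_rng(spec.seed)
    d0, d1, d2 = spec.durations_s
    t = np.arange(0.0, d0 + d1 + d2, spec.dt_s)
    signal = np.empty_like(t)
    phase = np.empty(len(t), dtype="U16")

    in0 = t < d0
    in1 = (t >= d0) & (t < d0 + d1)
    in2 = t >= d0 + d1
    signal[in0] = spec.f_initial
    phase[in0] = PHASE_BASELINE
    signal[in1] = spec.f_dit + (spec.f_initial - spec.f_dit) * np.exp(
        -(t[in1] - d0) / spec.tau_dit_s
    )
    phase[in1] = PHASE_DITHIONITE
    start2 = signal[in1][-1] if in1.any() else spec.f_dit
    signal[in2] = spec.f_triton + (start2 - spec.f_triton) * np.exp(
        -(t[in2] - d0 - d1) / spec.tau_triton_s
    )
    phase[in2] = PHASE_TRITON

    if spec.noise_sigma > 0:
        signal = signal + rng.normal(0.0, spec.noise_sigma * spec.f_initial, len(t))

    planted = permeability_from_levels(spec.f_initial, spec.f_dit, spec.f_triton)
    return AssayTrace(time=t, signal=signal, phase=phase), planted
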