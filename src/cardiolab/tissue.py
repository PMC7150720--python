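"""Monodomain tissue conduction on desk-scale 1D cables, rings and 2D sheets.

The tissue equation couples the single-cell reaction term to diffusion of the
membrane potential,

    dV/dt = -(I_ion + I_stim) + D * laplacian(V),

integrated by reaction–diffusion operator splitting: the cellular reaction
step reuses the single-cell kernel at every node, then an explicit
finite-difference diffusion step with no-flux (mirrored) boundaries is
applied to V.  With D = 0 the tissue trajectory therefore reduces *exactly*
to independent single cells.

Geometries:

* cable — 1D strand, optionally zoned transmurally (endo | mid | epi, the
  2 mm sub-endocardial and sub-epicardial shells of the ventricular wall
  with midmyocardium between);
* ring — 1D closed loop (periodic), the classic anatomical-reentry
  preparation used here for sustained-reentry wavelength measurements;
* sheet — 2D isotropic sheet for S1-S2 cross-field spiral induction.

The diffusion coefficient is calibrated once so a WT planar wave conducts at
the target velocity (70 cm/s) and is then held fixed across mutation
conditions, so wavelength differences between conditions reflect
repolarization (APD), not conduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import ionic_cell as ic
from . import protocols as pr
from .exceptions import (
    ConfigurationError,
    InsufficientReentryError,
    PropagationFailure,
)

D_DEFAULT = 0.00154       # cm^2/ms, base-model value for ~70 cm/s at dx 0.025
DX_DEFAULT = 0.025        # cm
DT_TISSUE = 0.02          # ms
STABILITY_SAFETY = 0.8
EAT_THRESHOLD = -40.0     # mV, upstroke crossing for activation time
REPOL_FRACTION = 0.9      # EDT level

CABLE_LENGTH = 1.5        # cm, transmural wall thickness
SHELL_THICKNESS = 0.2     # cm, endo and epi shells (2 mm each)


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------

@dataclass
class TissueGrid:
    """A 1D or 2D monodomain grid of coupled myocytes."""

    Y: np.ndarray                 # (19, n) state
    cell_types: np.ndarray        # (n,) int codes 0 endo / 1 mid / 2 epi
    gks: np.ndarray               # (n,) mS/µF
    gto: np.ndarray               # (n,) mS/µF
    ik1_variants: np.ndarray      # (n,) int codes
    dx: float                     # cm
    D: tuple                      # (Dx, Dy) cm^2/ms; Dy unused in 1D
    topology: str                 # "cable" | "ring" | "sheet"
    shape: tuple                  # (n,) or (ny, nx)
    condition: str = "WT"
    t: float = 0.0

    def __post_init__(self):
        if self.dx <= 0:
            raise ConfigurationError("dx must be positive")
        if min(self.D) < 0:
            raise ConfigurationError("diffusion coefficients must be >= 0")
        if self.topology not in ("cable", "ring", "sheet"):
            raise ConfigurationError(f"unknown topology {self.topology!r}")
        if not set(np.unique(self.cell_types)) <= {0, 1, 2}:
            raise ConfigurationError("unknown cell-type code in layout")

    @property
    def n_nodes(self) -> int:
        return self.Y.shape[1]

    def check_stability(self, dt: float):
        dsum = self.D[0] + (self.D[1] if self.topology == "sheet" else 0.0)
        if dsum > 0:
            dt_max = STABILITY_SAFETY * self.dx ** 2 / (2.0 * dsum)
            if dt > dt_max:
                raise ConfigurationError(
                    f"dt = {dt} ms violates the explicit-diffusion stability "
                    f"bound ({dt_max:.4f} ms at dx = {self.dx} cm)")


def _node_arrays(cell_types, cond):
    c = ic.condition(cond)
    ct = np.asarray(cell_types, dtype=np.int64)
    names = np.array(ic.CELL_TYPES)
    gks = np.array([ic.GKS_BY_TYPE[names[k]] for k in ct])
    gto = np.array([ic.GTO_BY_TYPE[names[k]] for k in ct])
    ik1v = np.full(len(ct), c.variant, dtype=np.int64)
    return ct, gks, gto, ik1v, c


def transmural_layout(n_nodes: int, dx: float,
                      shell: float = SHELL_THICKNESS) -> np.ndarray:
    """Endo | mid | epi zoning along a cable: 2 mm shells at each end."""
    x = np.arange(n_nodes) * dx
    length = (n_nodes - 1) * dx
    ct = np.full(n_nodes, 1, dtype=np.int64)          # mid
    ct[x < shell] = 0                                  # endo
    ct[x > length - shell] = 2                         # epi
    return ct


def make_cable(cond="WT", length: float = CABLE_LENGTH,
               dx: float = DX_DEFAULT, D: float = D_DEFAULT,
               cell_types="transmural") -> TissueGrid:
    """1D strand; ``cell_types`` is 'transmural', a single type name, or an
    explicit int-code array."""
    n = int(round(length / dx)) + 1
    if isinstance(cell_types, str):
        if cell_types == "transmural":
            ct = transmural_layout(n, dx)
        elif cell_types in ic.CELL_TYPES:
            ct = np.full(n, ic.CELL_TYPES.index(cell_types), dtype=np.int64)
        else:
            raise ConfigurationError(f"unknown layout {cell_types!r}")
    else:
        ct = np.asarray(cell_types, dtype=np.int64)
        if len(ct) != n:
            raise ConfigurationError("cell-type array length mismatch")
    ct, gks, gto, ik1v, c = _node_arrays(ct, cond)
    Y = np.repeat(ic._Y0[:, None], n, axis=1)
    return TissueGrid(Y=Y, cell_types=ct, gks=gks, gto=gto,
                      ik1_variants=ik1v, dx=dx, D=(D, 0.0),
                      topology="cable", shape=(n,), condition=c.label)


def make_ring(cond="WT", circumference: float = 25.0,
              dx: float = DX_DEFAULT, D: float = D_DEFAULT,
              cell_type: str = "epi") -> TissueGrid:
    """1D closed loop of a single cell type (anatomical-reentry pathway)."""
    n = int(round(circumference / dx))
    ct = np.full(n, ic.CELL_TYPES.index(cell_type), dtype=np.int64)
    ct, gks, gto, ik1v, c = _node_arrays(ct, cond)
    Y = np.repeat(ic._Y0[:, None], n, axis=1)
    return TissueGrid(Y=Y, cell_types=ct, gks=gks, gto=gto,
                      ik1_variants=ik1v, dx=dx, D=(D, 0.0),
                      topology="ring", shape=(n,), condition=c.label)


def make_sheet(cond="WT", Lx: float = 6.0, Ly: float = 6.0,
               dx: float = DX_DEFAULT, D: float = D_DEFAULT,
               cell_type: str = "epi") -> TissueGrid:
    """2D isotropic sheet of a single cell type."""
    nx = int(round(Lx / dx)) + 1
    ny = int(round(Ly / dx)) + 1
    n = nx * ny
    ct = np.full(n, ic.CELL_TYPES.index(cell_type), dtype=np.int64)
    ct, gks, gto, ik1v, c = _node_arrays(ct, cond)
    Y = np.repeat(ic._Y0[:, None], n, axis=1)
    return TissueGrid(Y=Y, cell_types=ct, gks=gks, gto=gto,
                      ik1_variants=ik1v, dx=dx, D=(D, D),
                      topology="sheet", shape=(ny, nx), condition=c.label)


# ---------------------------------------------------------------------------
# Integration kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _diffuse_1d(V, D, dx, dt, periodic):
    n = V.shape[0]
    lap = np.empty(n)
    for i in range(1, n - 1):
        lap[i] = V[i - 1] + V[i + 1] - 2.0 * V[i]
    if periodic:
        lap[0] = V[n - 1] + V[1] - 2.0 * V[0]
        lap[n - 1] = V[n - 2] + V[0] - 2.0 * V[n - 1]
    else:
        lap[0] = 2.0 * (V[1] - V[0])
        lap[n - 1] = 2.0 * (V[n - 2] - V[n - 1])
    c = D * dt / (dx * dx)
    for i in range(n):
        V[i] += c * lap[i]


@njit(cache=True)
def _diffuse_2d(V, ny, nx, Dx, Dy, dx, dt):
    lap = np.empty(ny * nx)
    for r in range(ny):
        for q in range(nx):
            i = r * nx + q
            vl = V[i - 1] if q > 0 else V[i + 1]
            vr = V[i + 1] if q < nx - 1 else V[i - 1]
            vu = V[i - nx] if r > 0 else V[i + nx]
            vd = V[i + nx] if r < ny - 1 else V[i - nx]
            lap[i] = (Dx * (vl + vr - 2.0 * V[i]) +
                      Dy * (vu + vd - 2.0 * V[i]))
    c = dt / (dx * dx)
    for i in range(ny * nx):
        V[i] += c * lap[i]


@njit(cache=True)
def _run_tissue(Y, ct, gks, gto, ik1v, Dx, Dy, dx, dt, nsteps, ny, nx,
                periodic, stim_start, stim_end, stim_amp, stim_mask,
                rec_stride, block_until, block_mask, y_rest, rec_ca,
                INF, RLF, CF, IK1T):
    """Advance a grid ``nsteps`` steps, recording V every ``rec_stride``.

    Stimuli: for each protocol entry k, nodes with stim_mask[k] get
    stim_amp[k] between stim_start[k] and stim_end[k].  Nodes in
    ``block_mask`` are clamped to the resting state until ``block_until``
    (used to enforce unidirectional initiation on rings).  With ``rec_ca``
    the cytosolic calcium field is recorded alongside V.
    """
    n = Y.shape[1]
    n_rec = nsteps // rec_stride + 1
    movie = np.empty((n_rec, n))
    ca_movie = np.empty((n_rec, n)) if rec_ca else np.empty((1, 1))
    times = np.empty(n_rec)
    movie[0] = Y[0]
    if rec_ca:
        ca_movie[0] = Y[3]
    times[0] = 0.0
    istim = np.zeros(n)
    k_rec = 1
    for step in range(nsteps):
        t = step * dt
        for i in range(n):
            istim[i] = 0.0
        for k in range(stim_start.shape[0]):
            if stim_start[k] <= t < stim_end[k]:
                for i in range(n):
                    if stim_mask[k, i]:
                        istim[i] += stim_amp[k]
        ic._advance_nodes(Y, ct, gks, gto, ik1v, istim, dt,
                          INF, RLF, CF, IK1T)
        if ny > 1:
            _diffuse_2d(Y[0], ny, nx, Dx, Dy, dx, dt)
        elif Dx > 0.0:
            _diffuse_1d(Y[0], Dx, dx, dt, periodic)
        if t < block_until:
            for i in range(n):
                if block_mask[i]:
                    for s in range(Y.shape[0]):
                        Y[s, i] = y_rest[s]
        if (step + 1) % rec_stride == 0:
            movie[k_rec] = Y[0]
            if rec_ca:
                ca_movie[k_rec] = Y[3]
            times[k_rec] = (step + 1) * dt
            k_rec += 1
    return times[:k_rec], movie[:k_rec], ca_movie[:k_rec] if rec_ca else ca_movie


# ---------------------------------------------------------------------------
# Runs
# ---------------------------------------------------------------------------

@dataclass
class TissueRun:
    """Space–time membrane-potential record of one tissue simulation."""

    grid: TissueGrid
    t: np.ndarray                 # ms, recorded frames
    V: np.ndarray                 # (n_frames, n_nodes) mV
    stim_times: np.ndarray        # ms, onset of each stimulus protocol entry
    dt: float = DT_TISSUE
    reentrant: bool = False
    Ca: np.ndarray | None = None  # (n_frames, n_nodes) mM, if recorded
    meta: dict = field(default_factory=dict)

    @property
    def dx(self) -> float:
        return self.grid.dx

    def node_series(self, i: int):
        return self.t, self.V[:, i]

    def last_activation_time(self, threshold: float = EAT_THRESHOLD):
        """Latest upstroke threshold crossing anywhere in the grid."""
        above = self.V >= threshold
        ups = ~above[:-1] & above[1:]
        if not ups.any():
            return None
        return float(self.t[1:][ups.any(axis=1)].max())


class Stimulus:
    """One stimulus protocol entry: nodes in ``mask`` receive ``amp`` pA/pF
    from ``start`` for ``duration`` ms."""

    def __init__(self, start: float, mask: np.ndarray,
                 amp: float = -52.0, duration: float = 1.0):
        self.start = float(start)
        self.duration = float(duration)
        self.amp = float(amp)
        self.mask = np.asarray(mask, dtype=np.bool_)


def run_tissue(grid: TissueGrid, duration: float, stimuli,
               dt: float = DT_TISSUE, rec_interval: float = 1.0,
               block_until: float = -1.0,
               block_mask: np.ndarray | None = None,
               record_ca: bool = False) -> TissueRun:
    """Integrate a grid for ``duration`` ms under a stimulus protocol."""
    grid.check_stability(dt)
    if not stimuli:
        raise ConfigurationError("at least one stimulus entry required")
    n = grid.n_nodes
    starts = np.array([s.start for s in stimuli])
    ends = np.array([s.start + s.duration for s in stimuli])
    amps = np.array([s.amp for s in stimuli])
    masks = np.zeros((len(stimuli), n), dtype=np.bool_)
    for k, s in enumerate(stimuli):
        if s.mask.shape != (n,):
            raise ConfigurationError("stimulus mask shape mismatch")
        masks[k] = s.mask
    bmask = (np.zeros(n, dtype=np.bool_) if block_mask is None
             else np.asarray(block_mask, dtype=np.bool_))
    ny, nx = (grid.shape if len(grid.shape) == 2 else (1, grid.shape[0]))
    tabs = ic.get_tables(dt)
    nsteps = int(round(duration / dt))
    rec_stride = max(int(round(rec_interval / dt)), 1)
    times, movie, ca_movie = _run_tissue(
        grid.Y, grid.cell_types, grid.gks, grid.gto, grid.ik1_variants,
        grid.D[0], grid.D[1], grid.dx, dt, nsteps, ny, nx,
        grid.topology == "ring", starts, ends, amps, masks,
        rec_stride, block_until, bmask, ic._Y0.copy(), record_ca, *tabs)
    grid.t += duration
    return TissueRun(grid=grid, t=times, V=movie, stim_times=starts, dt=dt,
                     Ca=ca_movie if record_ca else None)


def step_tissue(grid: TissueGrid, dt: float = DT_TISSUE,
                I_stim: np.ndarray | None = None) -> TissueGrid:
    """Advance a grid one reaction–diffusion step in place."""
    grid.check_stability(dt)
    istim = (np.zeros(grid.n_nodes) if I_stim is None
             else np.asarray(I_stim, float))
    tabs = ic.get_tables(dt)
    ic._advance_nodes(grid.Y, grid.cell_types, grid.gks, grid.gto,
                      grid.ik1_variants, istim, dt, *tabs)
    ny, nx = (grid.shape if len(grid.shape) == 2 else (1, grid.shape[0]))
    if ny > 1:
        _diffuse_2d(grid.Y[0], ny, nx, grid.D[0], grid.D[1], grid.dx, dt)
    elif grid.D[0] > 0.0:
        _diffuse_1d(grid.Y[0], grid.D[0], grid.dx, dt,
                    grid.topology == "ring")
    grid.t += dt
    return grid


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def _activation_time(t, v, threshold=EAT_THRESHOLD):
    above = v >= threshold
    ups = np.nonzero(~above[:-1] & above[1:])[0]
    if len(ups) == 0:
        return np.nan
    i = ups[0]
    return t[i] + (t[i + 1] - t[i]) * (threshold - v[i]) / (v[i + 1] - v[i])


def measure_cv(run: TissueRun, probes: tuple | None = None) -> float:
    """Planar-wave conduction velocity (cm/s) between two probe nodes.

    Probes default to 25% and 75% of a cable, away from the boundaries.
    Raises PropagationFailure if the wave does not traverse both probes.
    """
    n = run.grid.n_nodes
    if probes is None:
        probes = (int(0.25 * n), int(0.75 * n))
    i1, i2 = probes
    t1 = _activation_time(run.t, run.V[:, i1])
    t2 = _activation_time(run.t, run.V[:, i2])
    if np.isnan(t1) or np.isnan(t2) or t2 <= t1:
        raise PropagationFailure(
            f"wave did not traverse probes {probes} (EAT {t1}, {t2})")
    dist = abs(i2 - i1) * run.dx
    return float(dist / (t2 - t1) * 1000.0)  # cm/ms -> cm/s


@dataclass
class ActivationMaps:
    """Per-node electrical activation (EAT) and deactivation (EDT) times."""

    eat: np.ndarray    # ms
    edt: np.ndarray    # ms
    n_unactivated: int = 0

    def __post_init__(self):
        good = ~np.isnan(self.eat) & ~np.isnan(self.edt)
        if np.any(self.edt[good] < self.eat[good]):
            raise ConfigurationError("EDT must be >= EAT node-wise")

    @property
    def min_eat(self) -> float:
        return float(np.nanmin(self.eat))

    @property
    def max_eat(self) -> float:
        return float(np.nanmax(self.eat))

    @property
    def max_edt(self) -> float:
        return float(np.nanmax(self.edt))

    @property
    def qrs_surrogate(self) -> float:
        """Total activation spread: max EAT - min EAT."""
        return self.max_eat - self.min_eat

    @property
    def qt_surrogate(self) -> float:
        """Repolarization completion span: max EDT - min EAT."""
        return self.max_edt - self.min_eat


def activation_maps(run: TissueRun, threshold: float = EAT_THRESHOLD,
                    repol_fraction: float = REPOL_FRACTION
                    ) -> ActivationMaps:
    """EAT/EDT maps of one paced beat.

    EAT is the first upstroke crossing of ``threshold`` per node; EDT the
    subsequent repolarization to ``repol_fraction`` toward the node's
    pre-stimulus diastolic potential.  Unactivated nodes are excluded with a
    warning.
    """
    nt, n = run.V.shape
    eat = np.full(n, np.nan)
    edt = np.full(n, np.nan)
    unact = 0
    for i in range(n):
        v = run.V[:, i]
        a = _activation_time(run.t, v, threshold)
        if np.isnan(a):
            unact += 1
            continue
        eat[i] = a
        iact = np.searchsorted(run.t, a)
        # pre-beat diastolic reference: the recording starts before the
        # stimulus, so the first frame holds the diastolic potential
        v_dia = v[0]
        v_peak = float(np.max(v[iact:]))
        level = v_dia + (1.0 - repol_fraction) * (v_peak - v_dia)
        seg = v[iact:]
        down = np.nonzero((seg[:-1] > level) & (seg[1:] <= level))[0]
        if len(down) == 0:
            unact += 1
            eat[i] = np.nan
            continue
        k = iact + down[0]
        edt[i] = run.t[k] + (run.t[k + 1] - run.t[k]) * \
            (v[k] - level) / (v[k] - v[k + 1])
    if unact:
        warnings.warn(f"{unact} node(s) excluded from activation maps "
                      "(no activation or no repolarization)")
    return ActivationMaps(eat=eat, edt=edt, n_unactivated=unact)


def maps_from_arrays(eat: np.ndarray, edt: np.ndarray) -> ActivationMaps:
    """Build ActivationMaps from precomputed arrays (testing/IO)."""
    return ActivationMaps(eat=np.asarray(eat, float),
                          edt=np.asarray(edt, float))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_diffusion(target_cv: float = 70.0, cond="WT",
                        dx: float = DX_DEFAULT, dt: float = DT_TISSUE,
                        cell_type: str = "epi", length: float = 2.0,
                        D0: float = D_DEFAULT, n_iter: int = 3) -> float:
    """Diffusion coefficient giving the target planar CV on a uniform cable.

    Iterates D <- D * (target/CV)^2 (CV scales with sqrt(D)).  Calibrated
    for the WT condition and then reused unchanged for mutants.
    """
    D = D0
    for _ in range(n_iter):
        grid = make_cable(cond, length=length, dx=dx, D=D,
                          cell_types=cell_type)
        stim = Stimulus(0.0, _edge_mask(grid, 0.05))
        run = run_tissue(grid, 60.0, [stim], dt=dt, rec_interval=0.1)
        cv = measure_cv(run)
        D *= (target_cv / cv) ** 2
    return D


def _edge_mask(grid: TissueGrid, depth_cm: float) -> np.ndarray:
    """Mask of nodes within depth_cm of the start of a 1D grid, or of the
    left edge column(s) of a sheet."""
    n = grid.n_nodes
    mask = np.zeros(n, dtype=np.bool_)
    k = max(int(round(depth_cm / grid.dx)), 1)
    if len(grid.shape) == 1:
        mask[:k] = True
    else:
        ny, nx = grid.shape
        for r in range(ny):
            mask[r * nx:r * nx + k] = True
    return mask


def endocardial_edge_mask(grid: TissueGrid) -> np.ndarray:
    """Stimulus mask emulating simultaneous Purkinje delivery: every node of
    the endocardial shell fires at once."""
    mask = grid.cell_types == 0
    if not mask.any():
        mask = _edge_mask(grid, 2 * grid.dx)
    return mask


# ---------------------------------------------------------------------------
# Reentry
# ---------------------------------------------------------------------------

def induce_spiral(sheet: TissueGrid, s1_time: float = 0.0,
                  s2_time: float = 250.0, s2_region: str = "quadrant",
                  duration: float = 1000.0, dt: float = DT_TISSUE,
                  rec_interval: float = 2.0,
                  persist_ms: float = 2000.0) -> TissueRun:
    """S1-S2 cross-field stimulation on a 2D sheet.

    S1 is a planar wave from the left edge; S2 depolarizes a region (default
    the lower-left quadrant) at ``s2_time``.  The run is flagged reentrant if
    activation persists ``persist_ms`` after the S2 (self-sustained
    activity); failure to induce is a recorded outcome, not an error.
    """
    if len(sheet.shape) != 2:
        raise ConfigurationError("induce_spiral requires a 2D sheet")
    ny, nx = sheet.shape
    n = sheet.n_nodes
    s1_mask = _edge_mask(sheet, 2 * sheet.dx)
    s2_mask = np.zeros(n, dtype=np.bool_)
    if s2_region == "quadrant":
        for r in range(ny // 2, ny):
            s2_mask[r * nx: r * nx + nx // 2] = True
    else:
        s2_mask[:] = np.asarray(s2_region, dtype=np.bool_)
    stimuli = [Stimulus(s1_time, s1_mask, duration=2.0),
               Stimulus(s2_time, s2_mask, duration=2.0)]
    run = run_tissue(sheet, duration, stimuli, dt=dt,
                     rec_interval=rec_interval)
    last = run.last_activation_time()
    s2_end = s2_time + 2.0
    run.reentrant = bool(last is not None and
                         last >= s2_end + persist_ms)
    run.meta["last_activation_ms"] = last
    run.meta["s2_time"] = s2_time
    return run


def initiate_ring_reentry(ring: TissueGrid, duration: float,
                          dt: float = DT_TISSUE,
                          rec_interval: float = 1.0,
                          block_ms: float = 150.0,
                          record_ca: bool = False) -> TissueRun:
    """Launch a unidirectional circulating wave on a ring.

    A stimulus fires a short arc while the retrograde arc is transiently
    clamped refractory, leaving a single wavefront that circulates if the
    wavelength fits the circumference.
    """
    if ring.topology != "ring":
        raise ConfigurationError("requires a ring grid")
    n = ring.n_nodes
    w = max(int(0.01 * n), 4)
    stim_mask = np.zeros(n, dtype=np.bool_)
    stim_mask[:w] = True
    block = np.zeros(n, dtype=np.bool_)
    block[n - 6 * w:] = True   # retrograde arc held at rest during initiation
    run = run_tissue(ring, duration, [Stimulus(0.0, stim_mask, duration=2.0)],
                     dt=dt, rec_interval=rec_interval,
                     block_until=block_ms, block_mask=block,
                     record_ca=record_ca)
    last = run.last_activation_time()
    run.reentrant = bool(last is not None and last >= run.t[-1] - 300.0)
    run.meta["last_activation_ms"] = last
    return run


def reentry_wavelength(run: TissueRun, probe: int | None = None,
                       threshold: float = EAT_THRESHOLD,
                       n_frames: int = 5) -> dict:
    """Wavelength (cm) of a sustained reentrant wave, two ways.

    * ``arc`` — excited-tissue arc length: mean length of tissue with
      V above threshold over the final frames;
    * ``cv_apd`` — local conduction velocity times local APD at a probe node.

    Raises InsufficientReentryError if the run is not sustained.
    """
    if not run.reentrant:
        raise InsufficientReentryError(
            "run is not flagged reentrant; wavelength undefined")
    n = run.grid.n_nodes
    # (i) excited arc length
    arcs = []
    for frame in run.V[-n_frames:]:
        arcs.append(np.sum(frame >= threshold) * run.dx)
    wl_arc = float(np.mean(arcs))

    # (ii) CV_local x APD_local at a probe
    if probe is None:
        probe = n // 2
    t, v = run.node_series(probe)
    above = v >= threshold
    ups = np.nonzero(~above[:-1] & above[1:])[0]
    if len(ups) < 2:
        raise InsufficientReentryError("probe saw fewer than two activations")
    # local CV from activation delay to a neighbour ~1 cm downstream
    # (wide enough that frame-rate quantization of activation times is small)
    k = max(int(1.0 / run.dx), 2)
    j = (probe + k) % n
    t1 = _last_activation(t, run.V[:, probe], threshold)
    t2 = _last_activation(t, run.V[:, j], threshold)
    if t1 is None or t2 is None or abs(t2 - t1) < 1e-9:
        raise InsufficientReentryError("local CV not measurable at probe")
    cv_local = k * run.dx / abs(t2 - t1) * 1000.0    # cm/s
    # local APD from the last complete excursion at the probe
    i0, i1 = ups[-2], ups[-1]
    apd_local = _excited_duration(t, v, i0, i1, threshold)
    wl_cvapd = cv_local * apd_local / 1000.0          # cm
    return {"arc": wl_arc, "cv_apd": float(wl_cvapd),
            "cv_local": float(cv_local), "apd_local": float(apd_local),
            "period": float(t[ups[-1]] - t[ups[-2]])}


def _last_activation(t, v, threshold):
    above = v >= threshold
    ups = np.nonzero(~above[:-1] & above[1:])[0]
    if len(ups) == 0:
        return None
    i = ups[-1]
    return t[i] + (t[i + 1] - t[i]) * (threshold - v[i]) / (v[i + 1] - v[i])


def _excited_duration(t, v, i0, i1, threshold):
    """Time V stays above threshold after the upstroke at index i0."""
    seg = v[i0:i1 + 1]
    above = seg >= threshold
    downs = np.nonzero(above[:-1] & ~above[1:])[0]
    if len(downs) == 0:
        return float(t[i1] - t[i0])
    j = i0 + downs[0]
    return float(t[j] - t[i0])
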