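"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its arguments and a seed: rerunning
with the same seed is bit-identical.  Ground truth (the parameter values
used) travels with each artifact via :class:`GroundTruth`, so downstream
fitters can be validated by closure.

The molecular generators emulate three end-states of a short-peptide
self-assembly run: a fully *dispersed* solution, a liquid *droplet*
(condensate), and an ordered *fibril*.  Peptides are small rigid atom sets
(three residues of N, amide H, backbone C, carbonyl O) — enough geometry to
exercise SASA, contacts, and donor/acceptor roles without any force field.
Trajectories are morphs (linear centroid interpolation plus jitter), not
dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ArgumentError, GenerationError
from .structure import Configuration, Trajectory, DEFAULT_CONTACT_CUTOFF_NM
from .imaging import ImageField
from .kinetics import CoalescenceEvent, FrapTrace, KineticTrace, TurbidityCurve

UINT16_MAX = 65535.0

# --------------------------------------------------------------------------
# peptide template


def peptide_template() -> dict[str, np.ndarray]:
    """Rigid 12-atom tripeptide template (positions in nm, centered later).

    Per residue: amide N (donor) with its H, a backbone carbon, and a
    carbonyl O (acceptor).  The template is laid out so that identical
    copies stacked along +y at the fibril spacing place each N–H directly
    over the O of the peptide below, satisfying the geometric H-bond
    criterion by construction.
    """
    positions, radii, elements = [], [], []
    donor_h_local, acceptors = [], []
    for i in range(3):
        x = 0.36 * i
        base = len(positions)
        positions += [
            [x, 0.0, 0.0],        # N  (donor heavy)
            [x, -0.105, 0.0],     # H  (amide hydrogen)
            [x + 0.17, 0.06, 0.0],  # C  (backbone carbon)
            [x, 0.18, 0.0],       # O  (carbonyl acceptor)
        ]
        radii += [0.155, 0.110, 0.170, 0.152]
        elements += ["N", "H", "C", "O"]
        donor_h_local += [base + 1, -1, -1, -1]
        acceptors += [False, False, False, True]
    pos = np.asarray(positions)
    pos -= pos.mean(axis=0)
    return {
        "positions": pos,
        "radii": np.asarray(radii),
        "elements": np.asarray(elements, dtype=object),
        "donor_h_local": np.asarray(donor_h_local, dtype=int),
        "is_acceptor": np.asarray(acceptors, dtype=bool),
    }


def _template_diameter(tpl: dict[str, np.ndarray]) -> float:
    pos = tpl["positions"]
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max())) + 2.0 * float(tpl["radii"].max())


@dataclass
class GeometryParams:
    """Knobs for the molecular generators.

    ``droplet_packing_fraction`` plays the role of concentration: it sets
    how tightly peptides pack inside the condensate sphere.  Species
    fractions must sum to 1.
    """

    box_edge: float = 20.0  # nm
    fibril_spacing: float = 0.48  # nm, lattice period along the fibril axis
    droplet_packing_fraction: float = 0.4
    atoms_per_peptide: int = 12
    peptide_species_mix: dict[str, float] = field(
        default_factory=lambda: {"FFM": 0.5, "MFF": 0.5}
    )

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise ArgumentError("box_edge must be positive")
        if self.fibril_spacing <= 0:
            raise ArgumentError("fibril_spacing must be positive")
        if not 0.0 < self.droplet_packing_fraction < 1.0:
            raise ArgumentError("droplet_packing_fraction must be in (0, 1)")
        tot = sum(self.peptide_species_mix.values())
        if abs(tot - 1.0) > 1e-9:
            raise ArgumentError("species fractions must sum to 1")
        if self.atoms_per_peptide != 12:
            raise ArgumentError("the rigid template has 12 atoms per peptide")


@dataclass
class GroundTruth:
    """The parameters that produced a synthetic artifact, for closure tests."""

    kind: str | None = None  # dispersed | droplet | fibril
    true_k_partition: float | None = None
    true_tau_frap: float | None = None  # s
    true_mobile_fraction: float | None = None
    true_eta_over_gamma: float | None = None  # s / um
    true_rate_k: float | None = None  # per unit time
    seed: int = 0
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


# --------------------------------------------------------------------------
# configurations and trajectories


def _assign_species(n: int, mix: dict[str, float], rng: np.random.Generator) -> np.ndarray:
    tags = sorted(mix)
    counts = {t: int(np.floor(mix[t] * n)) for t in tags}
    remainder = n - sum(counts.values())
    by_frac = sorted(tags, key=lambda t: (mix[t] * n) % 1.0, reverse=True)
    for t in by_frac[:remainder]:
        counts[t] += 1
    labels = np.concatenate([np.full(counts[t], t, dtype=object) for t in tags])
    return labels[rng.permutation(n)]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix gives a Haar-uniform rotation after sign fix.
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _build_configuration(
    centroids: np.ndarray,
    rotations: list[np.ndarray] | None,
    species: np.ndarray,
    box_edge: float | None,
) -> Configuration:
    tpl = peptide_template()
    n = len(centroids)
    m = len(tpl["positions"])
    positions = np.empty((n * m, 3))
    for p in range(n):
        local = tpl["positions"]
        if rotations is not None:
            local = local @ rotations[p].T
        positions[p * m:(p + 1) * m] = local + centroids[p]
    donor = np.tile(tpl["donor_h_local"], n)
    offs = np.repeat(np.arange(n) * m, m)
    donor = np.where(donor >= 0, donor + offs, -1)
    return Configuration(
        positions=positions,
        radii=np.tile(tpl["radii"], n),
        elements=np.tile(tpl["elements"], n),
        peptide_ids=np.repeat(np.arange(n), m),
        species=np.repeat(species, m),
        donor_h_index=donor,
        is_acceptor=np.tile(tpl["is_acceptor"], n),
        box_edge=box_edge,
    )


def gen_configuration(
    kind: str,
    n_peptides: int,
    geom: GeometryParams | None = None,
    seed: int = 0,
) -> Configuration:
    """Generate a dispersed, droplet, or fibril end-state configuration.

    * dispersed — centroids placed by rejection sampling with a minimum
      separation of (contact cutoff + peptide diameter), so no inter-peptide
      contact exists at the default cutoff.
    * droplet — peptides randomly packed inside a sphere sized from the
      packing fraction; dense enough that the contact graph is essentially
      one cluster and substantial surface is buried.
    * fibril — peptides on a straight 1D lattice with identical orientation;
      backbone donors and acceptors of neighbours satisfy the H-bond
      criterion by construction.
    """
    if kind not in ("dispersed", "droplet", "fibril"):
        raise ArgumentError(f"unknown configuration kind: {kind!r}")
    if n_peptides < 1:
        raise ArgumentError("n_peptides must be >= 1")
    geom = geom or GeometryParams()
    rng = np.random.default_rng(seed)
    tpl = peptide_template()
    diameter = _template_diameter(tpl)
    species = _assign_species(n_peptides, geom.peptide_species_mix, rng)

    if kind == "fibril":
        center = np.full(3, geom.box_edge / 2.0)
        centroids = np.tile(center, (n_peptides, 1))
        centroids[:, 1] += (np.arange(n_peptides) - (n_peptides - 1) / 2.0) * geom.fibril_spacing
        return _build_configuration(centroids, None, species, geom.box_edge)

    if kind == "dispersed":
        d_min = DEFAULT_CONTACT_CUTOFF_NM + diameter
        margin = diameter / 2.0
        lo, hi = margin, geom.box_edge - margin
        if hi <= lo:
            raise GenerationError(f"box_edge={geom.box_edge} too small for the peptide template")
        placed: list[np.ndarray] = []
        tries, max_tries = 0, 2000 * n_peptides
        while len(placed) < n_peptides:
            tries += 1
            if tries > max_tries:
                raise GenerationError(
                    f"could not place {n_peptides} dispersed peptides with separation "
                    f"{d_min:.2f} nm in box_edge={geom.box_edge} nm"
                )
            c = rng.uniform(lo, hi, 3)
            if all(np.linalg.norm(c - q) > d_min for q in placed):
                placed.append(c)
        rots = [_random_rotation(rng) for _ in range(n_peptides)]
        return _build_configuration(np.array(placed), rots, species, geom.box_edge)

    # droplet: the effective hydrated radius sets the condensate volume at
    # the requested packing fraction; the centroid exclusion keeps peptides
    # from collapsing onto each other while leaving inter-peptide atoms
    # within contact range, so the droplet reads as one connected cluster
    # with 25-35% of its dispersed-state surface buried.
    r_eff = 0.42
    v_pep = 4.0 / 3.0 * np.pi * r_eff**3
    r_sphere = (n_peptides * v_pep / geom.droplet_packing_fraction / (4.0 / 3.0 * np.pi)) ** (1.0 / 3.0)
    d_min = 0.51 * diameter
    r_place = max(r_sphere - 0.3, d_min)
    placed = []
    tries, max_tries = 0, 20000 * n_peptides
    while len(placed) < n_peptides:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"droplet_packing_fraction={geom.droplet_packing_fraction} infeasible: "
                f"could not place {n_peptides} peptides in sphere radius {r_sphere:.2f} nm"
            )
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        c = geom.box_edge / 2.0 + v * r_place * rng.random() ** (1.0 / 3.0)
        if all(np.linalg.norm(c - q) > d_min for q in placed):
            placed.append(c)
    rots = [_random_rotation(rng) for _ in range(n_peptides)]
    return _build_configuration(np.array(placed), rots, species, geom.box_edge)


def gen_trajectory(
    kind: str,
    n_frames: int,
    n_peptides: int,
    geom: GeometryParams | None = None,
    seed: int = 0,
    jitter_sd: float = 0.02,
) -> Trajectory:
    """Morph from a dispersed frame 0 to the requested end-state.

    Intermediate frames are linear interpolations of atom positions with
    seeded Gaussian jitter; the first and last frames exactly reproduce the
    single-configuration generators for the same seed.
    """
    if n_frames < 2:
        raise ArgumentError("n_frames must be >= 2")
    geom = geom or GeometryParams()
    start = gen_configuration("dispersed", n_peptides, geom, seed)
    end = gen_configuration(kind, n_peptides, geom, seed)
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n_frames):
        alpha = k / (n_frames - 1)
        pos = (1.0 - alpha) * start.positions + alpha * end.positions
        if 0 < k < n_frames - 1 and jitter_sd > 0:
            pos = pos + rng.normal(0.0, jitter_sd, pos.shape)
        frames.append(
            Configuration(
                positions=pos,
                radii=start.radii.copy(),
                elements=start.elements.copy(),
                peptide_ids=start.peptide_ids.copy(),
                species=end.species.copy(),
                donor_h_index=start.donor_h_index.copy(),
                is_acceptor=start.is_acceptor.copy(),
                box_edge=geom.box_edge,
            )
        )
    return Trajectory(frames=frames, times=np.arange(n_frames, dtype=float))


# --------------------------------------------------------------------------
# imaging


def gen_partition_image(
    k_true: float,
    n_droplets: int = 10,
    radius_px: tuple[float, float] = (5.0, 30.0),
    background_level: float = 80.0,
    noise_sd: float = 0.0,
    image_shape: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[ImageField, np.ndarray]:
    """Synthetic confocal droplet field with a prescribed true partition K.

    Disks of intensity ``k_true * background_level`` are placed without
    overlap on a uniform background; the noiseless disk mean over background
    median is exactly ``k_true``.  Gaussian noise is added and clipped to
    the 16-bit range.  Returns the image and the true label mask.
    """
    if k_true <= 0:
        raise ArgumentError("k_true must be positive")
    if background_level <= 0:
        raise ArgumentError("background_level must be positive")
    if k_true * background_level > UINT16_MAX:
        raise ArgumentError(
            "k_true * background_level exceeds the 16-bit range; lower background_level"
        )
    rng = np.random.default_rng(seed)
    h, w = image_shape
    rmin, rmax = radius_px
    placed: list[tuple[float, float, float]] = []
    tries, max_tries = 0, 5000 * n_droplets
    while len(placed) < n_droplets:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not place n_droplets={n_droplets} non-overlapping disks "
                f"of radius {rmin}-{rmax} px in a {h}x{w} image"
            )
        r = rng.uniform(rmin, rmax)
        cy = rng.uniform(r + 2, h - r - 2)
        cx = rng.uniform(r + 2, w - r - 2)
        if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 2) ** 2 for y, x, rr in placed):
            placed.append((cy, cx, r))
    img = np.full((h, w), background_level, dtype=float)
    mask = np.zeros((h, w), dtype=int)
    yy, xx = np.mgrid[0:h, 0:w]
    for label, (cy, cx, r) in enumerate(placed, start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        img[disk] = k_true * background_level
        mask[disk] = label
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, UINT16_MAX)
    return ImageField(pixels=img, pixel_size=1.0, bit_depth=16), mask


# --------------------------------------------------------------------------
# traces and events


def gen_frap_trace(
    tau: float,
    mobile_fraction: float,
    bleach_depth: float = 0.45,
    n_points: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_total: float | None = None,
    n_prebleach: int = 10,
) -> FrapTrace:
    """Exponential FRAP recovery with prescribed bleach depth and mobility.

    Pre-bleach intensity is normalized to 1.  Post-bleach the model is
    I(t) = P - (P - I0) exp(-(t - t_b)/tau) with I0 = 1 - bleach_depth and
    plateau P = I0 + mobile_fraction (1 - I0).  The default bleach depth of
    0.45 mirrors photobleaching to 40-50% of the initial level.
    """
    if tau <= 0:
        raise ArgumentError("tau must be positive")
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ArgumentError("mobile_fraction must be in [0, 1]")
    if not 0.0 < bleach_depth < 1.0:
        raise ArgumentError("bleach_depth must be in (0, 1)")
    if n_points < 2:
        raise ArgumentError("n_points must be >= 2")
    t_total = 5.0 * tau if t_total is None else t_total
    rng = np.random.default_rng(seed)
    dt_pre = t_total / n_points
    t_pre = np.arange(n_prebleach) * dt_pre
    t_bleach = n_prebleach * dt_pre
    t_post = t_bleach + np.linspace(0.0, t_total, n_points)
    i0 = 1.0 - bleach_depth
    plateau = i0 + mobile_fraction * (1.0 - i0)
    i_post = plateau - (plateau - i0) * np.exp(-(t_post - t_bleach) / tau)
    intensity = np.concatenate([np.ones(n_prebleach), i_post])
    times = np.concatenate([t_pre, t_post])
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.shape)
    intensity = np.clip(intensity, 0.0, None)
    return FrapTrace(times=times, intensity=intensity, bleach_index=n_prebleach)


def gen_coalescence_events(
    eta_over_gamma: float,
    radii: np.ndarray | list[float],
    noise_frac: float = 0.0,
    seed: int = 0,
) -> list[CoalescenceEvent]:
    """Coalescence relaxation times obeying tau = l * (eta/gamma).

    Multiplicative Gaussian noise: tau = l (eta/gamma) (1 + eps),
    eps ~ N(0, noise_frac).
    """
    radii = np.asarray(radii, dtype=float)
    if (radii <= 0).any():
        raise ArgumentError("all radii must be positive")
    if noise_frac < 0:
        raise ArgumentError("noise_frac must be >= 0")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_frac, len(radii)) if noise_frac > 0 else np.zeros(len(radii))
    return [
        CoalescenceEvent(tau=float(l * eta_over_gamma * (1.0 + e)), l=float(l))
        for l, e in zip(radii, eps)
    ]


def gen_kinetic_trace(
    model: str,
    k: float,
    n_points: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_max: float | None = None,
) -> KineticTrace:
    """Linear (y = k t) or pseudo-first-order (y = 1 - exp(-k t)) trace."""
    if model not in ("linear", "first_order"):
        raise ArgumentError(f"unknown kinetic model: {model!r}")
    if k <= 0:
        raise ArgumentError("k must be positive")
    if n_points < 2:
        raise ArgumentError("n_points must be >= 2")
    if t_max is None:
        t_max = 20.0 if model == "linear" else 5.0 / k
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n_points)
    y = k * t if model == "linear" else 1.0 - np.exp(-k * t)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, y.shape)
    return KineticTrace(times=t, signal=y, model_hint=model)


def gen_turbidity_series(
    n_cycles: int = 4,
    high_level: float = 1.0,
    low_level: float = 0.05,
    points_per_phase: int = 20,
    amplitude_decay: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TurbidityCurve:
    """Alternating condensed/dissolved turbidity plateaus over pH cycles.

    Cycle i has amplitude (high - low) * amplitude_decay**i above the low
    plateau; decay 1.0 models fully reversible phase cycling.
    """
    if n_cycles < 1:
        raise ArgumentError("n_cycles must be >= 1")
    if not high_level > low_level >= 0:
        raise ArgumentError("need high_level > low_level >= 0")
    rng = np.random.default_rng(seed)
    segments = []
    boundaries = []
    idx = 0
    for i in range(n_cycles):
        amp = (high_level - low_level) * amplitude_decay**i
        segments.append(np.full(points_per_phase, low_level + amp))
        segments.append(np.full(points_per_phase, low_level))
        boundaries.append((idx, idx + 2 * points_per_phase))
        idx += 2 * points_per_phase
    absorbance = np.concatenate(segments)
    if noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, noise_sd, absorbance.shape)
    absorbance = np.clip(absorbance, 0.0, None)
    return TurbidityCurve(
        times=np.arange(len(absorbance), dtype=float),
        absorbance=absorbance,
        cycle_boundaries=boundaries,
    )


def gen_turbidity_grid(
    ph_values: np.ndarray | list[float] | None = None,
    nacl_values: np.ndarray | list[float] | None = None,
    peak: float = 1.0,
    blank_mean: float = 0.04,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Turbidity over a (pH, NaCl) grid with one unimodal phase-separated bump.

    Returns a :class:`~phasekit.kinetics.PhaseDiagram` with the boolean map
    unset; pass it through ``build_phase_map`` to threshold it.
    """
    from .kinetics import PhaseDiagram

    ph = np.asarray(ph_values if ph_values is not None else np.arange(5.0, 12.5, 0.5))
    salt = np.asarray(nacl_values if nacl_values is not None else [0.0, 100.0, 500.0, 1000.0])
    rng = np.random.default_rng(seed)
    ph_c, salt_c = 8.75, salt.mean()
    turb = blank_mean + peak * np.exp(
        -(((ph[:, None] - ph_c) / 1.5) ** 2) - (((salt[None, :] - salt_c) / (np.ptp(salt) or 1.0)) ** 2)
    )
    if noise_sd > 0:
        turb = turb + rng.normal(0.0, noise_sd, turb.shape)
    return PhaseDiagram(ph_values=ph, nacl_values=salt, turbidity=np.clip(turb, 0.0, None))
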