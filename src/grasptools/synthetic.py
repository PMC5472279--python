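"""Ground-truthed synthetic inputs for every pipeline in the package.

Each generator is a pure function of its arguments including the seed, and
returns both the simulated measurement (image, curve, coordinate pair or
event table) and the ground truth used to plant it, so tests and examples
can score recovery without any external data.

The image generators emulate two situations:

* cultured cells — one DAPI-stained elliptical nucleus per cell with a
  cluster of Golgi fragments parked against it (``gen_cell_image``);
* tissue sections — annular seminiferous-tubule profiles containing
  marker-positive regions of prescribed areas (``gen_tissue_image``).

Shapes are kept analytically simple (ellipses and discs built from an
exact pixel budget) so that every recorded ground-truth area equals the
mask pixel count times the pixel area, with no thresholding ambiguity.
Noise is additive Gaussian clipped at zero; optics (PSF, shot noise, 3D)
are deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import FLOW_POPULATIONS, CalibratedImage, EventTable

__all__ = [
    "ImageGroundTruth",
    "CurveGroundTruth",
    "TwoStateStructure",
    "gen_cell_image",
    "gen_tissue_image",
    "gen_curve",
    "gen_two_state",
    "gen_flow_events",
    "four_pl",
    "boltzmann_sigmoid",
    "wiseman_one_site",
]

CURVE_MODELS = ("4PL", "boltzmann", "wiseman_one_site")


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class ImageGroundTruth:
    """Planted masks and areas for a synthetic image."""

    nucleus_mask: np.ndarray
    golgi_fragment_masks: list[np.ndarray]
    per_fragment_area_um2: list[float]
    pixel_size_um: float
    seed: int
    fragment_cell_ids: list[int] = field(default_factory=list)
    fragment_tubule_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        shape = self.nucleus_mask.shape
        covered = np.zeros(shape, dtype=int)
        for m, area in zip(self.golgi_fragment_masks, self.per_fragment_area_um2):
            if m.shape != shape:
                raise ValueError("fragment mask shape differs from nucleus mask")
            covered += m.astype(int)
            expect = int(m.sum()) * self.pixel_size_um**2
            if not math.isclose(expect, area, rel_tol=1e-12, abs_tol=1e-12):
                raise ValueError("recorded area inconsistent with mask pixel count")
        if covered.max(initial=0) > 1:
            raise ValueError("fragment masks overlap")

    def tubule_id_image(self) -> np.ndarray:
        """Int image of planted tubule ids (-1 background)."""
        out = np.full(self.nucleus_mask.shape, -1, dtype=int)
        for m, t in zip(self.golgi_fragment_masks, self.fragment_tubule_ids):
            out[m] = t
        return out

    def cell_id_image(self) -> np.ndarray:
        """Int image of planted cell ids (-1 background)."""
        out = np.full(self.nucleus_mask.shape, -1, dtype=int)
        for m, c in zip(self.golgi_fragment_masks, self.fragment_cell_ids):
            out[m] = c
        return out


@dataclass
class CurveGroundTruth:
    """True model and parameters behind a simulated assay curve."""

    model_name: str
    true_params: dict[str, float]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.model_name not in CURVE_MODELS:
            raise ValueError(f"unknown model {self.model_name!r}; expected one of {CURVE_MODELS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        p = self.true_params
        if self.model_name == "4PL" and p.get("hill", 1.0) == 0:
            raise ValueError("hill slope must be nonzero")
        if self.model_name == "wiseman_one_site" and p.get("K_A", 1.0) <= 0:
            raise ValueError("K_A must be positive")
        if self.model_name == "boltzmann" and p.get("slope_a", 1.0) <= 0:
            raise ValueError("boltzmann slope must be positive")


@dataclass
class TwoStateStructure:
    """Two-domain CA coordinate sets related by a known hinge rotation."""

    open_coords: np.ndarray
    closed_coords: np.ndarray
    domain1_index_range: tuple[int, int]   # half-open
    domain2_index_range: tuple[int, int]   # half-open
    true_angle_deg: float
    true_axis: np.ndarray

    def __post_init__(self) -> None:
        n = self.open_coords.shape[0]
        a0, a1 = self.domain1_index_range
        b0, b1 = self.domain2_index_range
        if (a0, a1) != (0, b0) or b1 != n:
            raise ValueError("index ranges must be disjoint and cover all atoms")
        if self.closed_coords.shape != self.open_coords.shape:
            raise ValueError("open/closed coordinate shapes differ")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _disc_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    n_pixels: int,
    occupied: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of exactly ``n_pixels`` free pixels nearest to ``center``.

    Distance ties are broken deterministically by (distance, row, col)
    ordering, so the planted area is exact by construction.  Pixels set in
    ``occupied`` are skipped, which lets adjacent fragments tile into a
    contiguous cluster while keeping their masks pairwise disjoint.
    """
    # restrict the candidate sort to a window around the center; the
    # window is grown until it holds enough free pixels, so the result
    # is identical to a full-image search
    half = int(math.ceil(math.sqrt(n_pixels / math.pi) * 2 + 4))
    while True:
        r0 = max(0, int(center[0]) - half)
        r1 = min(shape[0], int(center[0]) + half + 1)
        c0 = max(0, int(center[1]) - half)
        c1 = min(shape[1], int(center[1]) + half + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        free = np.ones(rr.shape, dtype=bool) if occupied is None else ~occupied[r0:r1, c0:c1]
        if free.sum() >= n_pixels:
            d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
            order = np.lexsort((cc.ravel(), rr.ravel(), d2.ravel()))
            order = order[free.ravel()[order]]
            # accept only if the farthest chosen pixel is safely inside
            # the window (otherwise grow and re-search)
            chosen = order[:n_pixels]
            if math.sqrt(d2.ravel()[chosen[-1]]) <= half - 1 or (
                r0 == 0 and c0 == 0 and r1 == shape[0] and c1 == shape[1]
            ):
                mask = np.zeros(shape, dtype=bool)
                rows = rr.ravel()[chosen]
                cols = cc.ravel()[chosen]
                mask[rows, cols] = True
                return mask
        if r0 == 0 and c0 == 0 and r1 == shape[0] and c1 == shape[1]:
            raise RuntimeError("image too crowded to place region")
        half *= 2


def _ellipse_profile(shape, center, radii):
    """Normalized elliptical distance field; <=1 inside the ellipse."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.sqrt(((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2)


def _add_noise(img: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd == 0:
        return img
    return np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, None)


# ---------------------------------------------------------------------------
# cell images
# ---------------------------------------------------------------------------

def gen_cell_image(
    n_cells: int,
    fragments_per_cell: int,
    fragment_area_um2: float,
    pixel_size_um: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    nucleus_radius_um: float = 3.0,
    max_tries: int = 200,
) -> tuple[CalibratedImage, ImageGroundTruth]:
    """Simulate a 2-channel field of cultured cells.

    The DAPI channel holds ``n_cells`` elliptical nuclei with a smooth
    radial intensity falloff; the Golgi channel holds, per cell,
    ``fragments_per_cell`` disc-shaped fragments of ``fragment_area_um2``
    each, clustered against the nucleus rim.  Fragment masks are pairwise
    disjoint and their recorded areas are exact pixel budgets.

    Raises
    ------
    RuntimeError
        If a fragment cannot be placed without overlap within
        ``max_tries`` attempts (never silently truncates).
    """
    if n_cells < 1 or fragments_per_cell < 1:
        raise ValueError("n_cells and fragments_per_cell must be positive")
    if fragment_area_um2 <= 0 or pixel_size_um <= 0:
        raise ValueError("areas and pixel size must be positive")
    rng = np.random.default_rng(seed)

    frag_px = max(1, round(fragment_area_um2 / pixel_size_um**2))
    frag_r = math.sqrt(frag_px / math.pi)                      # px
    nuc_r = nucleus_radius_um / pixel_size_um                  # px
    # fragments sit on a ring around the cluster anchor, adjacent discs
    # nearly tangent, so a fragmented Golgi encloses a central void the
    # way a dispersed Golgi ribbon surrounds cytoplasm
    ring_r = 0.0 if fragments_per_cell == 1 else fragments_per_cell * 1.9 * frag_r / (2 * math.pi)
    cluster_r = ring_r + 2 * frag_r
    box = int(math.ceil(2.4 * (nuc_r + 2 * cluster_r + 4)))
    n_side = int(math.ceil(math.sqrt(n_cells)))
    shape = (n_side * box, n_side * box)

    dapi = np.zeros(shape)
    golgi = np.zeros(shape)
    nucleus_mask = np.zeros(shape, dtype=bool)
    frag_masks: list[np.ndarray] = []
    frag_areas: list[float] = []
    frag_cells: list[int] = []
    occupied = np.zeros(shape, dtype=bool)

    for cell in range(n_cells):
        gi, gj = divmod(cell, n_side)
        center = (gi * box + box / 2 + rng.uniform(-2, 2), gj * box + box / 2 + rng.uniform(-2, 2))
        radii = (nuc_r * rng.uniform(0.85, 1.0), nuc_r * rng.uniform(0.7, 0.9))
        prof = _ellipse_profile(shape, center, radii)
        inside = prof <= 1.0
        nucleus_mask |= inside
        dapi[inside] = np.maximum(dapi[inside], 40000.0 * (1.0 - 0.5 * prof[inside] ** 2))

        # anchor the Golgi cluster just outside the nucleus rim
        theta = rng.uniform(0, 2 * math.pi)
        anchor = (
            center[0] + (radii[0] + cluster_r + 1.5) * math.sin(theta),
            center[1] + (radii[1] + cluster_r + 1.5) * math.cos(theta),
        )
        phase = rng.uniform(0, 2 * math.pi)
        for k in range(fragments_per_cell):
            phi = phase + 2 * math.pi * k / fragments_per_cell
            c = (anchor[0] + ring_r * math.sin(phi), anchor[1] + ring_r * math.cos(phi))
            if not (
                frag_r < c[0] < shape[0] - frag_r - 1 and frag_r < c[1] < shape[1] - frag_r - 1
            ):
                raise RuntimeError(
                    f"fragment for cell {cell} falls outside the image; "
                    "reduce fragment size or count"
                )
            m = _disc_mask(shape, c, frag_px, occupied=occupied)
            occupied |= m
            frag_masks.append(m)
            frag_areas.append(int(m.sum()) * pixel_size_um**2)
            frag_cells.append(cell)
            golgi[m] = 30000.0

    dapi = _add_noise(dapi, noise_sd, rng)
    golgi = _add_noise(golgi, noise_sd, rng)
    img = CalibratedImage({"dapi": dapi, "golgi": golgi}, pixel_size_um)
    gt = ImageGroundTruth(
        nucleus_mask=nucleus_mask,
        golgi_fragment_masks=frag_masks,
        per_fragment_area_um2=frag_areas,
        pixel_size_um=pixel_size_um,
        seed=seed,
        fragment_cell_ids=frag_cells,
    )
    return img, gt


# ---------------------------------------------------------------------------
# tissue images
# ---------------------------------------------------------------------------

def gen_tissue_image(
    n_tubules: int,
    areas_um2_per_tubule: list[list[float]],
    pixel_size_um: float,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[CalibratedImage, ImageGroundTruth]:
    """Simulate a tissue section of annular tubule profiles.

    Each tubule is an annulus in the DAPI channel; the marker channel
    contains, inside the annulus band, one disc per requested area.
    Region masks carry their tubule ids in the ground truth.
    """
    if n_tubules < 1 or len(areas_um2_per_tubule) != n_tubules:
        raise ValueError("need one area list per tubule")
    rng = np.random.default_rng(seed)
    px2 = pixel_size_um**2

    areas_px = [[max(1, round(a / px2)) for a in areas] for areas in areas_um2_per_tubule]
    for areas, raw in zip(areas_px, areas_um2_per_tubule):
        for a_px, a_um in zip(areas, raw):
            if a_um <= 0:
                raise ValueError("region areas must be positive")
    max_frag_r = max((math.sqrt(max(a, default=1) / math.pi) for a in areas_px), default=1.0)
    max_per_tubule_n = max((len(a) for a in areas_px), default=0)
    band = max(6.0, 2.5 * max_frag_r)           # annulus half-width, px
    # mid radius: annulus must be wider than the band and long enough to
    # string the requested regions along its circumference
    r_mid = max(1.5 * band, 12.0, max_per_tubule_n * 2.6 * max_frag_r / (2 * math.pi))
    r_out = r_mid + band
    box = int(math.ceil(2.3 * r_out))
    n_side = int(math.ceil(math.sqrt(n_tubules)))
    shape = (n_side * box, n_side * box)
    if max_per_tubule_n > 0 and 2 * math.pi * r_mid < max_per_tubule_n * 2.5 * max_frag_r:
        raise ValueError("requested region areas too large for tubule annulus")

    dapi = np.zeros(shape)
    marker = np.zeros(shape)
    frag_masks: list[np.ndarray] = []
    frag_areas: list[float] = []
    frag_tubules: list[int] = []
    occupied = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]

    for t in range(n_tubules):
        gi, gj = divmod(t, n_side)
        center = (gi * box + box / 2.0, gj * box + box / 2.0)
        d = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
        annulus = (d >= r_mid - band) & (d <= r_mid + band)
        dapi[annulus] = np.maximum(dapi[annulus], 20000.0)

        # evenly spaced angular slots (jittered phase) keep planted
        # regions apart so segmentation sees one component per region
        n_here = len(areas_px[t])
        phase = rng.uniform(0, 2 * math.pi)
        for k, a_px in enumerate(areas_px[t]):
            theta = phase + 2 * math.pi * k / max(n_here, 1)
            c = (center[0] + r_mid * math.sin(theta), center[1] + r_mid * math.cos(theta))
            m = _disc_mask(shape, c, a_px)
            if (m & occupied).any():
                raise RuntimeError(
                    f"could not place region of {a_px} px in tubule {t}: "
                    "areas too large for the annulus"
                )
            occupied |= m
            frag_masks.append(m)
            frag_areas.append(int(m.sum()) * px2)
            frag_tubules.append(t)
            marker[m] = 30000.0

    dapi = _add_noise(dapi, noise_sd, rng)
    marker = _add_noise(marker, noise_sd, rng)
    img = CalibratedImage({"dapi": dapi, "golgi": marker}, pixel_size_um)
    gt = ImageGroundTruth(
        nucleus_mask=np.zeros(shape, dtype=bool),
        golgi_fragment_masks=frag_masks,
        per_fragment_area_um2=frag_areas,
        pixel_size_um=pixel_size_um,
        seed=seed,
        fragment_tubule_ids=frag_tubules,
    )
    return img, gt


# ---------------------------------------------------------------------------
# assay curves
# ---------------------------------------------------------------------------

def four_pl(x_log_molar, top, bottom, log_ic50, hill):
    """Four-parameter logistic in log10 concentration (variable slope)."""
    x = np.asarray(x_log_molar, dtype=float)
    with np.errstate(over="ignore"):  # saturated tail: 1/(1+inf) -> 0 is exact
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - x) * hill))


def boltzmann_sigmoid(t_c, f_min, f_max, tm_c, slope_a):
    """Boltzmann melt sigmoid: f = f_min + (f_max-f_min)/(1+exp((Tm-T)/a))."""
    t = np.asarray(t_c, dtype=float)
    return f_min + (f_max - f_min) / (1.0 + np.exp((tm_c - t) / slope_a))


def wiseman_one_site(molar_ratio, n_sites, K_A, delta_H, cell_conc):
    """One-site binding isotherm: heat per mole of injectant vs molar ratio.

    Closed form of d(bound)/d(total ligand) for 1:n binding with
    association constant ``K_A`` (1/M) at cell (macromolecule)
    concentration ``cell_conc`` (M); returns ``delta_H`` units per mole.
    """
    xr = np.asarray(molar_ratio, dtype=float)          # [X]_t / [M]_t
    r = 1.0 / (n_sites * K_A * cell_conc)
    b = 1.0 + xr / n_sites + r
    s = np.sqrt(b * b - 4.0 * xr / n_sites)
    return delta_H / 2.0 * (1.0 + (2.0 - b) / s)


_MODEL_FUNCS = {
    "4PL": lambda x, p: four_pl(x, p["top"], p["bottom"], p["log_ic50"], p["hill"]),
    "boltzmann": lambda x, p: boltzmann_sigmoid(x, p["f_min"], p["f_max"], p["tm_c"], p["slope_a"]),
    "wiseman_one_site": lambda x, p: wiseman_one_site(
        x, p["n_sites"], p["K_A"], p["delta_H"], p["cell_conc"]
    ),
}


def gen_curve(gt: CurveGroundTruth, x_values) -> np.ndarray:
    """Evaluate the ground-truth model on ``x_values`` and add seeded noise.

    Returns an ``(n, 2)`` array of (x, y).  With ``noise_sd=0`` the y
    column equals the closed-form model to machine precision.
    """
    x = np.asarray(x_values, dtype=float)
    if gt.model_name == "boltzmann" and np.any(np.diff(x) <= 0):
        raise ValueError("boltzmann temperatures must be strictly increasing")
    y = _MODEL_FUNCS[gt.model_name](x, gt.true_params)
    if gt.noise_sd > 0:
        rng = np.random.default_rng(gt.seed)
        y = y + rng.normal(0.0, gt.noise_sd, x.shape)
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# two-state structures
# ---------------------------------------------------------------------------

def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Proper rotation about ``axis`` by ``angle_deg`` (Rodrigues form)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be nonzero")
    u = axis / norm
    th = math.radians(angle_deg)
    k = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + math.sin(th) * k + (1 - math.cos(th)) * (k @ k)


def gen_two_state(
    n_atoms_per_domain: int,
    angle_deg: float,
    axis=(0.0, 0.0, 1.0),
    jitter_sd: float = 0.0,
    seed: int = 0,
    domain_sep: float = 25.0,
) -> TwoStateStructure:
    """Build an open/closed pair of two compact pseudo-domains.

    Domain 1 stays fixed; domain 2 is rotated by ``angle_deg`` about
    ``axis`` through the inter-domain interface centroid, then both
    closed-state domains receive isotropic Gaussian jitter of
    ``jitter_sd`` angstroms (crystal-noise stand-in).
    """
    if n_atoms_per_domain < 3:
        raise ValueError("need at least 3 atoms per domain")
    rng = np.random.default_rng(seed)
    d1 = rng.normal(0.0, 6.0, (n_atoms_per_domain, 3))
    d2 = rng.normal(0.0, 6.0, (n_atoms_per_domain, 3)) + np.array([domain_sep, 0.0, 0.0])
    open_coords = np.vstack([d1, d2])

    pivot = (d1.mean(axis=0) + d2.mean(axis=0)) / 2.0
    rot = rotation_matrix(axis, angle_deg)
    d2_closed = (d2 - pivot) @ rot.T + pivot
    closed = np.vstack([d1, d2_closed])
    if jitter_sd > 0:
        closed = closed + rng.normal(0.0, jitter_sd, closed.shape)

    u = np.asarray(axis, dtype=float)
    return TwoStateStructure(
        open_coords=open_coords,
        closed_coords=closed,
        domain1_index_range=(0, n_atoms_per_domain),
        domain2_index_range=(n_atoms_per_domain, 2 * n_atoms_per_domain),
        true_angle_deg=angle_deg,
        true_axis=u / np.linalg.norm(u),
    )


# ---------------------------------------------------------------------------
# flow-cytometry events
# ---------------------------------------------------------------------------

def gen_flow_events(
    n_events: int,
    fractions,
    mean_intensities,
    cv: float,
    seed: int = 0,
    source: str = "synthetic",
) -> EventTable:
    """Draw a 4-population log-normal DNA-content mixture.

    ``fractions`` (summing to 1) and strictly increasing
    ``mean_intensities`` define the populations in the fixed order
    ES < RS < 2C < 4C; ``cv`` is the per-population coefficient of
    variation of intensity.
    """
    fractions = np.asarray(fractions, dtype=float)
    means = np.asarray(mean_intensities, dtype=float)
    if fractions.shape != (4,) or means.shape != (4,):
        raise ValueError("need exactly four fractions and four means")
    if abs(fractions.sum() - 1.0) > 1e-9 or np.any(fractions < 0):
        raise ValueError("fractions must be non-negative and sum to 1")
    if np.any(np.diff(means) <= 0) or np.any(means <= 0):
        raise ValueError("mean intensities must be positive and strictly increasing")
    if cv <= 0:
        raise ValueError("cv must be positive")

    rng = np.random.default_rng(seed)
    pop = rng.choice(4, size=n_events, p=fractions)
    sigma = math.sqrt(math.log1p(cv**2))          # log-normal shape from CV
    mu = np.log(means) - sigma**2 / 2.0           # so E[intensity] = mean
    intensity = np.exp(rng.normal(mu[pop], sigma))
    label = np.array([FLOW_POPULATIONS[i] for i in pop], dtype=object)
    return EventTable(intensity=intensity, label=label, source=source)
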