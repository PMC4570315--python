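"""Synthetic wine panels, dye-bead responses, and rendered array images.

This module generates ground-truthed stand-ins for everything the bench
produces: per-sample taste-chemical profiles with a two-cluster
(sweet/dry) structure, saturating colour responses of the eight dye-bead
conjugates, Gaussian-peak absorbance spectra, and before/after photos of
the 8-well sensor chip.  Every generator is a pure function of its seed.

The dye response is modelled as a Langmuir-form saturation: the colour
change of dye ``d`` in channel ``ch`` is

    delta[d, ch] = sum_c  S[d, ch, c] * conc_c / (conc_c + K_c)

where ``S`` is a signed sensitivity matrix (RGB counts at full
saturation) and ``K_c`` the half-saturation concentration of chemical
``c``.  Colorimetric dye binding saturates, so a bounded monotone
response is the natural choice; the linear-additive mixing across
chemicals keeps the model analytically checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .chemicals import CHEMICALS, CLUSTER_RANGES, SWEET_FRACTION

__all__ = [
    "ChemProfile",
    "DyeResponseModel",
    "ArrayImagePair",
    "DYE_NAMES",
    "generate_panel",
    "default_dye_model",
    "simulate_color_response",
    "render_image_pair",
    "simulate_spectrum",
    "WAVELENGTHS_NM",
]

#: Canonical dye order: well 1..8 of the chip, row-major.
DYE_NAMES: tuple[str, ...] = (
    "alizarin",
    "calconcarboxylic_acid",
    "cresol_red",
    "crystal_violet",
    "fluorescein",
    "methylthymol_blue",
    "phenol_red",
    "xylenol_orange",
)

#: Spectral support of the simulated spectrophotometer, per-nm.
WAVELENGTHS_NM = np.arange(400, 781)


@dataclass
class ChemProfile:
    """Taste-chemical concentrations (mg/L) of one wine sample."""

    sample_id: str
    concentrations: dict[str, float]
    cluster: str  # "sweet" | "dry"

    def __post_init__(self) -> None:
        if self.cluster not in ("sweet", "dry"):
            raise ValueError(f"unknown cluster {self.cluster!r}")
        missing = [c for c in CHEMICALS if c not in self.concentrations]
        if missing:
            raise ValueError(f"profile {self.sample_id!r} missing chemicals: {missing}")
        for name, conc in self.concentrations.items():
            if conc < 0:
                raise ValueError(
                    f"negative concentration {conc} for {name!r} in {self.sample_id!r}"
                )

    def as_vector(self, order: tuple[str, ...] = CHEMICALS) -> np.ndarray:
        return np.array([self.concentrations[c] for c in order], dtype=float)


@dataclass
class DyeResponseModel:
    """Colour and spectral response of the eight dye-bead conjugates.

    Attributes
    ----------
    dyes : dye names, well order.
    baseline_rgb : (8, 3) resting colour of each bead well, 0-255.
    sensitivity : (8, 3, n_chem) signed RGB change at full saturation.
    half_saturation : (n_chem,) mg/L at which a chemical reaches half
        of its maximal colour effect.
    peaks : per dye, an (n_peaks, 3) array of (center_nm, width_nm, height)
        Gaussian absorbance peaks for the spectral model.
    spectral_gain : per dye, an (n_peaks, n_chem) array of fractional
        peak-height modulation at full saturation.
    """

    dyes: tuple[str, ...]
    baseline_rgb: np.ndarray
    sensitivity: np.ndarray
    half_saturation: np.ndarray
    peaks: list[np.ndarray] = field(default_factory=list)
    spectral_gain: list[np.ndarray] = field(default_factory=list)
    chemicals: tuple[str, ...] = CHEMICALS

    def __post_init__(self) -> None:
        self.baseline_rgb = np.asarray(self.baseline_rgb, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        self.half_saturation = np.asarray(self.half_saturation, dtype=float)
        n_dye, n_chem = len(self.dyes), len(self.chemicals)
        if self.baseline_rgb.shape != (n_dye, 3):
            raise ValueError("baseline_rgb must be (n_dyes, 3)")
        if self.sensitivity.shape != (n_dye, 3, n_chem):
            raise ValueError("sensitivity must be (n_dyes, 3, n_chemicals)")
        if np.any(self.half_saturation <= 0):
            raise ValueError("half_saturation must be positive")
        if np.any(self.baseline_rgb < 0) or np.any(self.baseline_rgb > 255):
            raise ValueError("baseline_rgb outside 8-bit channel range")
        flat = self.sensitivity.reshape(n_dye, -1)
        for i in range(n_dye):
            for j in range(i + 1, n_dye):
                if np.allclose(flat[i], flat[j]):
                    raise ValueError(
                        f"dyes {self.dyes[i]!r} and {self.dyes[j]!r} share an "
                        "identical sensitivity row"
                    )

    # -- serialisation -------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "dyes": list(self.dyes),
            "chemicals": list(self.chemicals),
            "baseline_rgb": self.baseline_rgb.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "half_saturation": self.half_saturation.tolist(),
            "peaks": [p.tolist() for p in self.peaks],
            "spectral_gain": [g.tolist() for g in self.spectral_gain],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "DyeResponseModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            dyes=tuple(doc["dyes"]),
            baseline_rgb=np.array(doc["baseline_rgb"]),
            sensitivity=np.array(doc["sensitivity"]),
            half_saturation=np.array(doc["half_saturation"]),
            peaks=[np.array(p) for p in doc["peaks"]],
            spectral_gain=[np.array(g) for g in doc["spectral_gain"]],
            chemicals=tuple(doc["chemicals"]),
        )


@dataclass
class ArrayImagePair:
    """Before/after photos of the 8-well chip plus rendering ground truth.

    Rasters are float64 H x W x 3 in 0-255 units (quantised only on PNG
    export) so that noiseless renders are exactly recoverable.
    """

    before: np.ndarray
    after: np.ndarray
    centers: np.ndarray  # (n_wells, 2) as (row, col)
    radius: float
    truth_delta: np.ndarray  # (n_wells, 3), pre-clip
    clip_warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# panel generation
# ---------------------------------------------------------------------------

def _draw_concentration(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Log-uniform within (lo, hi]; plain uniform when the range touches 0."""
    if lo <= 0:
        return float(rng.uniform(lo, hi))
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_panel(n_base: int, n_mixtures: int, seed: int) -> list[ChemProfile]:
    """Generate ``n_base`` wines plus ``n_mixtures`` pairwise blends.

    Base wines are drawn log-uniformly within per-cluster concentration
    ranges, with roughly 30% assigned to the sweet group.  Each mixture
    is a convex combination (uniform random weight) of two distinct base
    wines from the same group, so the two-cluster score separation is
    preserved; blends fall back to cross-group pairing only when a group
    has fewer than two members.
    """
    if n_base < 2:
        raise ValueError(f"n_base must be >= 2, got {n_base}")
    if n_mixtures < 0:
        raise ValueError(f"n_mixtures must be >= 0, got {n_mixtures}")
    rng = np.random.default_rng(seed)

    n_sweet = int(round(n_base * SWEET_FRACTION))
    n_sweet = min(max(n_sweet, 1), n_base - 1)
    clusters = np.array(["sweet"] * n_sweet + ["dry"] * (n_base - n_sweet))
    rng.shuffle(clusters)

    profiles: list[ChemProfile] = []
    for i in range(n_base):
        cl = str(clusters[i])
        ranges = CLUSTER_RANGES[cl]
        conc = {c: _draw_concentration(rng, *ranges[c]) for c in CHEMICALS}
        profiles.append(ChemProfile(f"base{i + 1:02d}", conc, cl))

    by_cluster = {
        cl: [p for p in profiles if p.cluster == cl] for cl in ("sweet", "dry")
    }
    for m in range(n_mixtures):
        eligible = [cl for cl in ("sweet", "dry") if len(by_cluster[cl]) >= 2]
        if eligible:
            cl = eligible[int(rng.integers(len(eligible)))]
            a, b = rng.choice(len(by_cluster[cl]), size=2, replace=False)
            pa, pb = by_cluster[cl][a], by_cluster[cl][b]
            label = cl
        else:  # degenerate tiny panels: blend across groups
            a, b = rng.choice(n_base, size=2, replace=False)
            pa, pb = profiles[a], profiles[b]
            label = None
        w = float(rng.uniform(0.0, 1.0))
        conc = {
            c: w * pa.concentrations[c] + (1 - w) * pb.concentrations[c]
            for c in CHEMICALS
        }
        if label is None:
            label = pa.cluster if w >= 0.5 else pb.cluster
        profiles.append(ChemProfile(f"mix{m + 1:02d}", conc, label))
    return profiles


# ---------------------------------------------------------------------------
# default dye model
# ---------------------------------------------------------------------------

# Resting well colours loosely evoking the dyes' visual appearance; all are
# far from the dark chip background so well detection is unambiguous.
_BASELINES = np.array(
    [
        [190, 110, 80],   # alizarin
        [160, 75, 105],   # calconcarboxylic acid
        [190, 160, 75],   # cresol red
        [130, 85, 175],   # crystal violet
        [150, 190, 90],   # fluorescein
        [90, 130, 190],   # methylthymol blue
        [190, 90, 90],    # phenol red
        [195, 140, 80],   # xylenol orange
    ],
    dtype=float,
)


def default_dye_model(seed: int = 20150818) -> DyeResponseModel:
    """The fixed, seeded dye-bead model shipped with the package.

    Sensitivities are signed and sparse (each dye responds appreciably to
    an overlapping subset of chemicals), so no two dyes share a response
    row; their magnitude is scaled so the summed full-saturation colour
    change stays within the 8-bit gamut of the mid-range baselines (a
    camera cannot record a colour outside its channel range, so an
    in-gamut response model keeps the rendered images faithful to the
    underlying deltas).  Half-saturation constants sit at the geometric
    midpoint of each chemical's global concentration range, centering
    the dyes' dynamic range on the concentrations encountered in wine.
    """
    from .chemicals import CONCENTRATION_RANGES

    rng = np.random.default_rng(seed)
    n_chem = len(CHEMICALS)
    sens = rng.uniform(-25.0, 25.0, size=(8, 3, n_chem))
    sens *= rng.random(size=(8, 3, n_chem)) < 0.6
    half_sat = np.array(
        [
            np.sqrt(max(CONCENTRATION_RANGES[c][0], 10.0) * CONCENTRATION_RANGES[c][1])
            for c in CHEMICALS
        ]
    )
    peaks, gains = [], []
    for _ in range(8):
        n_peaks = int(rng.integers(1, 4))
        centers = rng.uniform(420, 760, n_peaks)
        widths = rng.uniform(15, 60, n_peaks)
        heights = rng.uniform(0.2, 1.2, n_peaks)
        peaks.append(np.column_stack([centers, widths, heights]))
        gains.append(rng.uniform(-0.8, 3.0, size=(n_peaks, n_chem)))
    return DyeResponseModel(
        dyes=DYE_NAMES,
        baseline_rgb=_BASELINES.copy(),
        sensitivity=sens,
        half_saturation=half_sat,
        peaks=peaks,
        spectral_gain=gains,
    )


# ---------------------------------------------------------------------------
# responses, spectra, images
# ---------------------------------------------------------------------------

def _langmuir(conc: np.ndarray, half_sat: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        out = conc / (conc + half_sat)
    return np.where(conc == 0, 0.0, out)


def simulate_color_response(
    profile: ChemProfile,
    model: DyeResponseModel,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Ground-truth (8, 3) colour change of the array for one sample."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    unknown = [c for c in profile.concentrations if c not in model.chemicals]
    if unknown:
        raise ValueError(f"unknown chemical(s) in profile: {unknown}")
    conc = profile.as_vector(model.chemicals)
    sat = _langmuir(conc, model.half_saturation)  # (n_chem,)
    delta = model.sensitivity @ sat  # (8, 3)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        delta = delta + rng.normal(0.0, noise_sd, size=delta.shape)
    return delta


def well_layout(
    rows: int = 2, cols: int = 4, radius: float = 16.0, pitch: float = 48.0,
    margin: float = 30.0,
) -> tuple[np.ndarray, float, tuple[int, int]]:
    """Row-major circular well centers plus the raster shape holding them."""
    centers = np.array(
        [[margin + r * pitch, margin + c * pitch] for r in range(rows) for c in range(cols)],
        dtype=float,
    )
    height = int(margin * 2 + (rows - 1) * pitch)
    width = int(margin * 2 + (cols - 1) * pitch)
    return centers, radius, (height, width)


#: Uniform chip-background colour, distinct from every well baseline.
BACKGROUND_RGB = np.array([30.0, 30.0, 30.0])


def render_image_pair(
    deltas: np.ndarray,
    model: DyeResponseModel,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
    layout: tuple[np.ndarray, float, tuple[int, int]] | None = None,
) -> ArrayImagePair:
    """Render the before/after photo pair for one sample's colour deltas.

    Wells are flat-filled (baseline, then baseline + delta, clipped to the
    8-bit range with a recorded warning) on a uniform dark background;
    optional per-pixel Gaussian noise emulates sensor read noise.
    """
    deltas = np.asarray(deltas, dtype=float)
    centers, radius, (h, w) = layout if layout is not None else well_layout()
    n_wells = len(centers)
    if deltas.shape != (n_wells, 3):
        raise ValueError(f"deltas must be ({n_wells}, 3)")
    if np.any(centers[:, 0] - radius < 0) or np.any(centers[:, 0] + radius >= h) or \
       np.any(centers[:, 1] - radius < 0) or np.any(centers[:, 1] + radius >= w):
        raise ValueError("well layout does not fit inside the raster")

    before = np.empty((h, w, 3))
    before[:] = BACKGROUND_RGB
    after = before.copy()
    yy, xx = np.mgrid[0:h, 0:w]
    clip_warnings: list[str] = []
    for i, (cy, cx) in enumerate(centers):
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        base = model.baseline_rgb[i]
        target = base + deltas[i]
        clipped = np.clip(target, 0.0, 255.0)
        if not np.allclose(clipped, target):
            clip_warnings.append(
                f"well {i}: after-colour {np.round(target, 2).tolist()} clipped to channel range"
            )
        before[mask] = base
        after[mask] = clipped
    if pixel_noise_sd > 0:
        rng = np.random.default_rng(seed)
        before = before + rng.normal(0.0, pixel_noise_sd, before.shape)
        after = after + rng.normal(0.0, pixel_noise_sd, after.shape)
    return ArrayImagePair(
        before=before,
        after=after,
        centers=centers,
        radius=radius,
        truth_delta=deltas.copy(),
        clip_warnings=clip_warnings,
    )


def simulate_spectrum(
    dye: str, chemical: str, conc: float, model: DyeResponseModel
) -> np.ndarray:
    """Per-nm absorbance (400-780 nm) of one dye at one analyte level.

    Each Gaussian peak's height is modulated by the same Langmuir
    saturation term that drives the colour response; absorbance is
    clamped at zero, so strongly negative gains bleach a peak at most to
    extinction.
    """
    if conc < 0:
        raise ValueError("conc must be >= 0")
    if dye not in model.dyes:
        raise ValueError(f"unknown dye {dye!r}")
    if chemical not in model.chemicals:
        raise ValueError(f"unknown chemical {chemical!r}")
    d = model.dyes.index(dye)
    c = model.chemicals.index(chemical)
    sat = float(
        _langmuir(np.array([conc]), model.half_saturation[c : c + 1])[0]
    )
    spec = np.zeros_like(WAVELENGTHS_NM, dtype=float)
    for (center, width, height), gain in zip(model.peaks[d], model.spectral_gain[d]):
        factor = max(0.0, 1.0 + gain[c] * sat)
        spec += height * factor * np.exp(-((WAVELENGTHS_NM - center) ** 2) / (2 * width**2))
    return spec


# ---------------------------------------------------------------------------
# file IO helpers
# ---------------------------------------------------------------------------

def panel_to_frame(profiles: list[ChemProfile]):
    """Panel as a DataFrame: sample_id, cluster, one column per chemical."""
    import pandas as pd

    rows = [
        {"sample_id": p.sample_id, "cluster": p.cluster, **p.concentrations}
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=["sample_id", "cluster", *CHEMICALS])


def panel_from_frame(frame) -> list[ChemProfile]:
    return [
        ChemProfile(
            row["sample_id"],
            {c: float(row[c]) for c in CHEMICALS},
            row["cluster"],
        )
        for _, row in frame.iterrows()
    ]


def save_image(raster: np.ndarray, path) -> None:
    """Quantise a float 0-255 raster to 8-bit RGB and write a PNG."""
    from PIL import Image

    arr = np.clip(np.rint(raster), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def load_image(path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=float)
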