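"""Seeded synthetic fluorescence-slide generator with ground truth.

Emulates the statistical structure the pipeline assumes for cardiac
biopsy slides: a nuclei channel (DAPI-like) showing bright elliptical
nuclei on a dark noisy background, and a damage channel
(gamma-H2A.X-like) showing small punctate foci placed inside nuclei
with a Poisson-distributed per-nucleus count.  Class effects are
encoded as distribution shifts:

* diseased vs control nuclei differ in size/eccentricity (altered
  nuclear morphology);
* poor-prognosis vs responding patients differ in the mean number of
  DNA-damage foci per nucleus.

Every output is reproducible bit-for-bit from (params, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import tifffile

from .core_imaging import ChannelRole, RasterImage


class GenerationError(RuntimeError):
    """Raised when non-overlapping nucleus packing fails."""


@dataclass(frozen=True)
class PhenotypeParams:
    """Distributional parameters of one synthetic phenotype (class).

    Defaults describe a control-like phenotype on a small test slide;
    cohort-level presets live in :func:`hf_class_params` and
    :func:`lvrr_class_params`.  Nuclei are rendered at small radii
    (a few pixels) on purpose, so the downstream bicubic enlargement
    step operates in the regime it exists for.
    """

    n_nuclei: int = 40
    nucleus_radius_mean: float = 5.0     # px, semi-major axis
    nucleus_radius_sd: float = 1.0
    eccentricity_mean: float = 0.3
    eccentricity_sd: float = 0.1
    foci_rate: float = 1.0               # mean Poisson foci per nucleus
    focus_radius: float = 1.5            # px
    foreground_intensity: float = 180.0
    focus_intensity: float = 200.0
    background_noise_sd: float = 8.0
    background_level: float = 20.0
    slide_height: int = 256
    slide_width: int = 256
    non_overlapping: bool = True
    margin_px: float = 4.0               # extra gap enforced between nuclei
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.nucleus_radius_mean <= 0 or self.focus_radius <= 0:
            raise ValueError("radii must be positive")
        if self.foci_rate < 0:
            raise ValueError("foci_rate must be >= 0")

    def replace(self, **kw) -> "PhenotypeParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class NucleusTruth:
    centroid: tuple[float, float]        # (row, col)
    axes: tuple[float, float]            # (semi-major, semi-minor), px
    orientation: float                   # radians
    area_px: float                       # analytic ellipse area, pi*a*b
    n_foci: int


@dataclass(frozen=True)
class GroundTruth:
    nuclei: tuple[NucleusTruth, ...]
    label: int
    seed: int

    @property
    def centroids(self) -> np.ndarray:
        if not self.nuclei:
            return np.zeros((0, 2))
        return np.array([n.centroid for n in self.nuclei])


def _sample_ellipses(params: PhenotypeParams, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipse parameters."""
    placed: list[tuple[float, float, float, float, float]] = []
    h, w = params.slide_height, params.slide_width
    max_tries = 200 * max(params.n_nuclei, 1)
    tries = 0
    while len(placed) < params.n_nuclei:
        if tries > max_tries:
            raise GenerationError(
                f"could not pack {params.n_nuclei} non-overlapping nuclei "
                f"into a {h}x{w} slide after {max_tries} attempts"
            )
        tries += 1
        a = max(1.5, rng.normal(params.nucleus_radius_mean, params.nucleus_radius_sd))
        ecc = float(np.clip(
            rng.normal(params.eccentricity_mean, params.eccentricity_sd), 0.0, 0.95
        ))
        b = a * float(np.sqrt(1.0 - ecc**2))
        theta = rng.uniform(0, np.pi)
        r = rng.uniform(a + 1, h - a - 1) if h > 2 * (a + 1) else h / 2
        c = rng.uniform(a + 1, w - a - 1) if w > 2 * (a + 1) else w / 2
        if params.non_overlapping:
            ok = all(
                np.hypot(r - r2, c - c2) >= (a + a2 + params.margin_px)
                for r2, c2, a2, _, _ in placed
            )
            if not ok:
                continue
        placed.append((r, c, a, b, theta))
    return placed


def _render_ellipse(canvas: np.ndarray, r: float, c: float, a: float, b: float,
                    theta: float, value: float) -> None:
    """Paint a filled rotated ellipse onto ``canvas`` (max blend)."""
    h, w = canvas.shape
    pad = int(np.ceil(a)) + 2
    r0, r1 = max(0, int(r) - pad), min(h, int(r) + pad + 1)
    c0, c1 = max(0, int(c) - pad), min(w, int(c) + pad + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr, dc = rr - r, cc - c
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    region = canvas[r0:r1, c0:c1]
    region[inside] = np.maximum(region[inside], value)


def generate_slide(
    params: PhenotypeParams, label: int = 0
) -> tuple[RasterImage, RasterImage, GroundTruth]:
    """Render one dual-channel synthetic slide plus its ground truth.

    Returns ``(nuclei_channel, damage_channel, truth)``; both channels
    are 8-bit and share the slide dimensions.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.slide_height, params.slide_width
    nuc = np.zeros((h, w), dtype=np.float32)
    dmg = np.zeros((h, w), dtype=np.float32)

    ellipses = _sample_ellipses(params, rng)
    records = []
    for r, c, a, b, theta in ellipses:
        _render_ellipse(nuc, r, c, a, b, theta, params.foreground_intensity)
        n_foci = int(rng.poisson(params.foci_rate))
        for _ in range(n_foci):
            # place the focus centre inside the ellipse (uniform in the
            # unit disk mapped through the ellipse axes)
            rad = np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            u, v = a * rad * np.cos(ang), b * rad * np.sin(ang)
            ct, st = np.cos(theta), np.sin(theta)
            fr, fc = r + u * ct - v * st, c + u * st + v * ct
            _render_ellipse(dmg, fr, fc, params.focus_radius,
                            params.focus_radius, 0.0, params.focus_intensity)
        records.append(NucleusTruth(
            centroid=(r, c), axes=(a, b), orientation=theta,
            area_px=float(np.pi * a * b), n_foci=n_foci,
        ))

    # float32 and strictly in-place: whole-slide noise dominates the
    # render cost, so avoid every large temporary
    def _finish(chan: np.ndarray) -> np.ndarray:
        if params.background_noise_sd > 0:
            out = rng.standard_normal(size=(h, w), dtype=np.float32)
            out *= np.float32(params.background_noise_sd)
            out += chan
        else:
            out = chan
        # +0.5 then truncation to uint8 (in RasterImage) rounds half-up
        out += np.float32(params.background_level + 0.5)
        np.clip(out, 0, 255, out=out)
        return out.astype(np.uint8)

    nuc = _finish(nuc)
    dmg = _finish(dmg)
    truth = GroundTruth(nuclei=tuple(records), label=label, seed=params.seed)
    return (
        RasterImage(nuc, bitdepth=8, channel_role=ChannelRole.NUCLEI),
        RasterImage(dmg, bitdepth=8, channel_role=ChannelRole.DAMAGE),
        truth,
    )


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------

def hf_class_params(**overrides) -> tuple[PhenotypeParams, PhenotypeParams]:
    """(control, diseased) phenotypes: disease shifts nuclear size up and
    makes nuclei markedly more elongated."""
    ctrl = PhenotypeParams(
        nucleus_radius_mean=4.5, nucleus_radius_sd=0.8,
        eccentricity_mean=0.25, eccentricity_sd=0.1,
        foci_rate=0.0,
    ).replace(**overrides)
    hf = ctrl.replace(
        nucleus_radius_mean=6.0, nucleus_radius_sd=1.0,
        eccentricity_mean=0.75, eccentricity_sd=0.1,
    )
    return ctrl, hf


def lvrr_class_params(
    foci_rate_positive: float = 0.5, foci_rate_negative: float = 5.0, **overrides
) -> tuple[PhenotypeParams, PhenotypeParams]:
    """(responder, non-responder) phenotypes: poor prognosis carries a
    10x higher mean DNA-damage focus count per nucleus."""
    pos = PhenotypeParams(foci_rate=foci_rate_positive).replace(**overrides)
    neg = pos.replace(foci_rate=foci_rate_negative)
    return pos, neg


def iter_cohort_slides(
    n_patients_per_class: int,
    class_params: tuple[PhenotypeParams, PhenotypeParams],
    seed: int,
    cohort: str = "LVRR_cohort",
):
    """Lazily yield ``(record, nuclei, damage, truth)`` per patient.

    Streaming counterpart of :func:`generate_cohort` for slide sizes
    where holding a whole cohort in memory is wasteful; per-patient
    seeds are drawn identically.
    """
    if n_patients_per_class < 1:
        raise ValueError("need at least one patient per class")
    master = np.random.default_rng(seed)
    patient_seeds = master.integers(0, 2**31 - 1, size=2 * n_patients_per_class)
    i = 0
    for label, params in enumerate(class_params):
        for k in range(n_patients_per_class):
            pid = f"P{label}{k:03d}"
            p = params.replace(seed=int(patient_seeds[i]))
            nuc, dmg, truth = generate_slide(p, label=label)
            yield {"patient_id": pid, "cohort": cohort, "label": label}, nuc, dmg, truth
            i += 1


def generate_cohort(
    n_patients_per_class: int,
    class_params: tuple[PhenotypeParams, PhenotypeParams],
    seed: int,
    out_dir: str | Path | None = None,
    cohort: str = "LVRR_cohort",
) -> tuple[list[dict], list[GroundTruth]]:
    """Generate one dual-channel slide per synthetic patient.

    Class 0 uses ``class_params[0]``, class 1 uses ``class_params[1]``;
    per-patient seeds are drawn deterministically from the master seed.
    If ``out_dir`` is given, slides are written as single-channel TIFFs
    plus ``patients.json`` and ``truth.csv``; the returned patient
    records then reference those files, otherwise they carry the images
    in memory under ``"channels"``.
    """
    if n_patients_per_class < 1:
        raise ValueError("need at least one patient per class")
    master = np.random.default_rng(seed)
    patient_seeds = master.integers(0, 2**31 - 1, size=2 * n_patients_per_class)
    records: list[dict] = []
    truths: list[GroundTruth] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    i = 0
    for label, params in enumerate(class_params):
        for k in range(n_patients_per_class):
            pid = f"P{label}{k:03d}"
            p = params.replace(seed=int(patient_seeds[i]))
            nuc, dmg, truth = generate_slide(p, label=label)
            rec: dict = {"patient_id": pid, "cohort": cohort, "label": label}
            if out_path is None:
                rec["channels"] = (nuc, dmg)
            else:
                nuc_file = out_path / f"{pid}_nuclei.tiff"
                dmg_file = out_path / f"{pid}_damage.tiff"
                tifffile.imwrite(nuc_file, nuc.pixels)
                tifffile.imwrite(dmg_file, dmg.pixels)
                rec["item_paths"] = [str(nuc_file), str(dmg_file)]
            records.append(rec)
            truths.append(truth)
            i += 1

    if out_path is not None:
        with open(out_path / "patients.json", "w") as fh:
            json.dump(
                [{k: v for k, v in r.items() if k != "channels"} for r in records],
                fh, indent=2,
            )
        rows = []
        for rec, truth in zip(records, truths):
            for j, n in enumerate(truth.nuclei):
                rows.append({
                    "patient_id": rec["patient_id"], "nucleus": j,
                    "row": n.centroid[0], "col": n.centroid[1],
                    "semi_major": n.axes[0], "semi_minor": n.axes[1],
                    "orientation": n.orientation, "area_px": n.area_px,
                    "n_foci": n.n_foci, "label": truth.label,
                })
        pd.DataFrame(rows).to_csv(out_path / "truth.csv", index=False)
    return records, truths
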