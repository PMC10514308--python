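"""Synthetic data with known ground truth for every pipeline stage.

Three generators: (1) per-cell smFISH measurement tables whose transcript
counts and promoter states are drawn jointly from the stationary two-state
law, with intensities proportional to counts under multiplicative noise and
a bimodal marker channel separating crystal cells from background cells;
(2) 2D images of Gaussian spots with Poisson or Gaussian noise; (3)
multinomial band read counts with planted binding occupancies for the
nucleosome-shift assay.  Every generator is deterministic under its seed.

Default scenario parameters are the fitted study conditions: wild-type
(k_on, k_off, k_prod) = (2.7, 3.7, 1524) with 184 cells and mutant
(0.19, 5.1, 571) with 340 cells, per mRNA degradation time.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import ArgumentError
from .telegraph import KineticParams, _as_rng, sample_counts_with_state
from .nucshift import NUCLEOSOME_BAND, SUPERSHIFT_BAND, BandReadCounts

__all__ = [
    "Scenario",
    "simulate_cell_table",
    "render_spot_image",
    "place_nonoverlapping_spots",
    "simulate_band_counts",
    "WILD_TYPE_PARAMS",
    "MUTANT_PARAMS",
]

WILD_TYPE_PARAMS = KineticParams(k_on=2.7, k_off=3.7, k_prod=1524.0)
MUTANT_PARAMS = KineticParams(k_on=0.19, k_off=5.1, k_prod=571.0)


@dataclass
class Scenario:
    """Study conditions for the synthetic smFISH experiment.

    ``genotypes`` maps genotype label -> telegraph parameters, ``n_cells``
    maps genotype label -> number of crystal cells.  ``background_fraction``
    is the fraction of all cells that are non-crystal background (no target
    expression, low marker).  Intensities are in arbitrary fluorescence
    units; a cell's total intensity is count * single-transcript intensity *
    lognormal multiplicative noise of the given CV.  The nascent site is
    rendered iff the promoter is ON, with a per-site RNA load of
    ``nascent_rna_min`` + Poisson(``nascent_rna_extra``) transcripts.
    """

    seed: int
    genotypes: dict = field(
        default_factory=lambda: {
            "wild_type": WILD_TYPE_PARAMS,
            "mutant": MUTANT_PARAMS,
        }
    )
    n_cells: dict = field(
        default_factory=lambda: {"wild_type": 184, "mutant": 340}
    )
    background_fraction: float = 0.5
    single_transcript_intensity: float = 10.0
    single_transcript_cv: float = 0.2
    intensity_cv: float = 0.15
    marker_crystal_mean: float = 100.0
    marker_background_mean: float = 1.0
    marker_log_sigma: float = 0.35
    nascent_rna_min: int = 4
    nascent_rna_extra: float = 4.0
    nascent_lag: float = 0.0  # reserved: delay between state and visibility

    def __post_init__(self):
        if self.seed is None:
            raise ArgumentError("a seed is mandatory for reproducibility")
        if not self.genotypes or set(self.genotypes) != set(self.n_cells):
            raise ArgumentError("genotypes and n_cells must share keys")
        for g, n in self.n_cells.items():
            if n < 1:
                raise ArgumentError(f"n_cells[{g!r}] must be >= 1")
        if self.single_transcript_intensity <= 0:
            raise ArgumentError("single-transcript intensity must be positive")
        if not 0 <= self.background_fraction < 1:
            raise ArgumentError("background_fraction must be in [0, 1)")
        self.genotypes = {
            g: p if isinstance(p, KineticParams) else KineticParams(**p)
            for g, p in self.genotypes.items()
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genotypes"] = {g: p.to_dict() for g, p in self.genotypes.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "Scenario":
        text = open(path).read()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d)


def _lognormal_factor(rng, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the requested CV."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def simulate_cell_table(scenario: Scenario) -> pd.DataFrame:
    """Per-cell smFISH measurement table with ground-truth columns.

    Crystal cells draw (count, promoter state) jointly from the stationary
    two-state law of their genotype; total intensity is proportional to the
    count with multiplicative noise; the nascent-site intensity is positive
    iff the promoter is ON.  Background cells express nothing and carry the
    low marker mode.  Ground truth lives in ``true_*`` columns.
    """
    rng = _as_rng(scenario.seed)
    i1 = scenario.single_transcript_intensity
    frames = []
    for genotype, params in scenario.genotypes.items():
        n_crystal = scenario.n_cells[genotype]
        f = scenario.background_fraction
        n_background = int(round(n_crystal * f / (1.0 - f)))
        counts, on = sample_counts_with_state(params, n_crystal, rng)

        noise = _lognormal_factor(rng, scenario.intensity_cv, n_crystal)
        total = counts * i1 * noise
        n_nas_rna = scenario.nascent_rna_min + rng.poisson(
            scenario.nascent_rna_extra, n_crystal
        )
        nas_noise = _lognormal_factor(rng, scenario.intensity_cv, n_crystal)
        nascent = np.where(on, n_nas_rna * i1 * nas_noise, 0.0)
        marker_c = rng.lognormal(
            math.log(scenario.marker_crystal_mean),
            scenario.marker_log_sigma,
            n_crystal,
        )
        frames.append(
            pd.DataFrame(
                {
                    "genotype": genotype,
                    "total_intensity": total,
                    "marker_intensity": marker_c,
                    "nascent_intensity": nascent,
                    "true_count": counts,
                    "true_on": on,
                    "true_crystal": True,
                }
            )
        )
        if n_background:
            marker_b = rng.lognormal(
                math.log(scenario.marker_background_mean),
                scenario.marker_log_sigma,
                n_background,
            )
            frames.append(
                pd.DataFrame(
                    {
                        "genotype": genotype,
                        "total_intensity": 0.0,
                        "marker_intensity": marker_b,
                        "nascent_intensity": 0.0,
                        "true_count": 0,
                        "true_on": False,
                        "true_crystal": False,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "cell_id", np.arange(len(table)))
    return table


# ---------------------------------------------------------------------------
# spot image rendering
# ---------------------------------------------------------------------------


def place_nonoverlapping_spots(
    n: int, shape: tuple[int, int], *, margin: int = 8, min_dist: float = 7.0, seed=0
) -> np.ndarray:
    """(row, col) centers at least ``min_dist`` apart, away from the border.

    Centers sit on a jittered grid, so placement is O(n) and deterministic.
    """
    rows = np.arange(margin, shape[0] - margin, min_dist)
    cols = np.arange(margin, shape[1] - margin, min_dist)
    if rows.size * cols.size < n:
        raise ArgumentError(
            f"cannot place {n} spots of spacing {min_dist} in shape {shape}"
        )
    rng = _as_rng(seed)
    grid = np.array([(r, c) for r in rows for c in cols])
    idx = rng.choice(len(grid), size=n, replace=False)
    jitter = rng.uniform(-1.0, 1.0, size=(n, 2))
    return grid[idx] + jitter


def render_spot_image(
    spots,
    shape: tuple[int, int],
    *,
    noise: str = "none",
    noise_sigma: float = 1.0,
    background: float = 0.0,
    seed=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a sum of elliptical Gaussian spots plus background and noise.

    ``spots`` rows are (row, col, amplitude, sigma_row, sigma_col); amplitude
    may be a total of several transcripts at the same site.  ``background``
    may be a scalar or an array of the image shape (e.g. a gradient).
    Returns (image, ground-truth table with analytic integrated intensities).
    ``noise``: "none", "poisson" (counts-like) or "gaussian" (additive,
    sd=``noise_sigma``).
    """
    spots = np.atleast_2d(np.asarray(spots, dtype=float))
    if spots.shape[1] != 5:
        raise ArgumentError("each spot is (row, col, amplitude, sigma_r, sigma_c)")
    if np.any(spots[:, 0] < 0) or np.any(spots[:, 0] > shape[0] - 1) or np.any(
        spots[:, 1] < 0
    ) or np.any(spots[:, 1] > shape[1] - 1):
        raise ArgumentError("spot centers must lie inside the image bounds")
    rr, cc = np.indices(shape)
    image = np.zeros(shape, dtype=float) + background
    truth = []
    for r0, c0, amp, sr, sc in spots:
        image += amp * np.exp(
            -((rr - r0) ** 2 / (2 * sr**2) + (cc - c0) ** 2 / (2 * sc**2))
        )
        truth.append(
            {
                "row": r0,
                "col": c0,
                "amplitude": amp,
                "sigma_r": sr,
                "sigma_c": sc,
                "integrated_intensity": 2.0 * math.pi * amp * sr * sc,
            }
        )
    if noise == "poisson":
        rng = _as_rng(seed)
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    elif noise == "gaussian":
        rng = _as_rng(seed)
        image = image + rng.normal(0.0, noise_sigma, size=shape)
    elif noise != "none":
        raise ArgumentError(f"unknown noise model {noise!r}")
    return image, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# band read counts
# ---------------------------------------------------------------------------


def simulate_band_counts(
    occupancies: pd.DataFrame | dict,
    depth: int,
    seed=0,
    *,
    control_template: str = "601",
    input_lane: str = "input",
) -> BandReadCounts:
    """Multinomial read counts per lane under planted binding occupancies.

    ``occupancies[template][lane]`` (dict of dicts or a DataFrame with
    templates as index, lanes as columns) is the bound fraction of that
    template in that lane: a template contributes (1 - occ) of its material
    to the free-nucleosome band and occ to the super-shifted band.  Each
    lane's ``depth`` reads are allocated multinomially across the
    (template, band) cells; an input lane (occupancy 0 everywhere) is added
    if not supplied.
    """
    if depth < 1:
        raise ArgumentError("depth must be >= 1")
    occ = pd.DataFrame(occupancies, dtype=float).T if isinstance(
        occupancies, dict
    ) else pd.DataFrame(occupancies, dtype=float)
    if ((occ < 0) | (occ > 1)).any().any() or occ.isna().any().any():
        raise ArgumentError("occupancies must lie in [0, 1]")
    if control_template not in occ.index:
        occ.loc[control_template] = 0.0
    if input_lane not in occ.columns:
        occ[input_lane] = 0.0
    occ[input_lane] = 0.0  # the input lane has no protein by definition
    rng = _as_rng(seed)
    rows = []
    templates = list(occ.index)
    for lane in occ.columns:
        o = occ[lane].to_numpy()
        weights = np.concatenate([(1.0 - o), o])  # nucleosome cells, then shift
        reads = rng.multinomial(depth, weights / weights.sum())
        for i, t in enumerate(templates):
            rows.append(
                {"template_id": t, "band": NUCLEOSOME_BAND, "lane": lane,
                 "reads": int(reads[i])}
            )
            rows.append(
                {"template_id": t, "band": SUPERSHIFT_BAND, "lane": lane,
                 "reads": int(reads[len(templates) + i])}
            )
    return BandReadCounts(
        pd.DataFrame(rows), control_template=control_template, input_lane=input_lane
    )
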