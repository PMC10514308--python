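"""Relative-shift statistics for the nucleosome electrophoretic binding assay.

Nucleosome templates (Widom-601 scaffolds carrying a binding motif at
different superhelix locations, plus the motif-free 601 control) are
incubated with increasing protein, run on a gel, and the bands sequenced.
Protein binding depletes a template's free-nucleosome band and populates a
super-shifted band.  The relative shift of template N in a lane is

    -log2( (reads_N / reads_601) / (reads_input_N / reads_input_601) )

for the chosen band, i.e. a ratio-of-ratios against the motif-free control
normalized by the no-protein input lane.  The double normalization cancels
sequencing depth, gel-excision and PCR biases: the control's shift is 0 by
construction and shifts are invariant to per-lane depth rescaling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .exceptions import (
    ArgumentError,
    InsufficientDataError,
    NonFiniteValueError,
    ParseError,
    StructureError,
)

__all__ = [
    "BandReadCounts",
    "RelativeShiftResult",
    "relative_shift",
    "summarize_titration",
    "NUCLEOSOME_BAND",
    "SUPERSHIFT_BAND",
    "TEMPLATE_REGISTRY",
    "EDGE_TEMPLATES",
]

NUCLEOSOME_BAND = "nucleosome"
SUPERSHIFT_BAND = "supershift"

# default registry: motif positions by superhelix location on the 601
# scaffold (R = right of the dyad, L = left), plus the motif-free control.
TEMPLATE_REGISTRY = [
    "601",
    "R0",
    "R0.5",
    "R4",
    "R4.5",
    "R6",
    "R6.5",
    "R7",
    "R8",
    "R6+R7",
    "L6+R7",
]
# positions near where DNA enters/exits the nucleosome
EDGE_TEMPLATES = ["R6", "R6.5", "R7", "R6+R7", "L6+R7"]


class BandReadCounts:
    """Read counts per (template, band, lane) with a designated control
    template and input (no-protein) lane."""

    REQUIRED = ("template_id", "band", "lane", "reads")

    def __init__(
        self,
        frame: pd.DataFrame,
        control_template: str = "601",
        input_lane: str = "input",
    ):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise StructureError(f"band-count table lacks columns {missing}")
        frame = frame.copy()
        for col in ("template_id", "band", "lane"):
            frame[col] = frame[col].astype(str)  # "601" must survive CSV I/O
        frame["reads"] = pd.to_numeric(frame["reads"], errors="raise")
        if (frame["reads"] < 0).any():
            raise ArgumentError("read counts must be non-negative")
        self.frame = frame
        self.control_template = control_template
        self.input_lane = input_lane
        self._validate()

    def _validate(self):
        if self.input_lane not in set(self.frame["lane"]):
            raise StructureError(f"input lane {self.input_lane!r} missing")
        for (band, lane), grp in self.frame.groupby(["band", "lane"]):
            if self.control_template not in set(grp["template_id"]):
                raise StructureError(
                    f"control template {self.control_template!r} missing from "
                    f"band {band!r}, lane {lane!r}"
                )
        # every lane must carry the same template set per band
        for band, grp in self.frame.groupby("band"):
            sets = grp.groupby("lane")["template_id"].apply(set)
            if len({frozenset(s) for s in sets}) != 1:
                raise StructureError(
                    f"lanes disagree on the template set in band {band!r}"
                )

    @property
    def lanes(self) -> list[str]:
        return list(pd.unique(self.frame["lane"]))

    @property
    def templates(self) -> list[str]:
        return list(pd.unique(self.frame["template_id"]))

    @property
    def bands(self) -> list[str]:
        return list(pd.unique(self.frame["band"]))

    @classmethod
    def from_csv(
        cls, path, control_template: str = "601", input_lane: str = "input"
    ) -> "BandReadCounts":
        try:
            frame = pd.read_csv(path)
        except Exception as exc:
            raise ParseError(f"cannot parse band-count CSV {path}: {exc}") from exc
        bad = frame.index[pd.to_numeric(frame.get("reads"), errors="coerce").isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ParseError(
                f"non-numeric reads value at row {bad[0] + 2} of {path}",
                row=int(bad[0]) + 2,
            )
        return cls(frame, control_template, input_lane)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


class RelativeShiftResult:
    """Relative shifts per (template, lane) for one band."""

    def __init__(self, table: pd.DataFrame, band: str, pseudocount: float,
                 control_template: str, input_lane: str):
        self.table = table  # columns: template_id, lane, relative_shift
        self.band = band
        self.pseudocount = pseudocount
        self.control_template = control_template
        self.input_lane = input_lane

    def pivot(self) -> pd.DataFrame:
        return self.table.pivot(
            index="template_id", columns="lane", values="relative_shift"
        )

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["band"] = self.band
        out["pseudocount"] = self.pseudocount
        out.to_csv(path, index=False)


def relative_shift(
    counts: BandReadCounts,
    band: str = NUCLEOSOME_BAND,
    pseudocount: float = 1.0,
) -> RelativeShiftResult:
    """Relative shift of every template in every non-input lane for ``band``.

    The pseudocount is added to every read count before forming ratios (the
    statistic is undefined at zero reads); the control template's shift is
    exactly 0 in every lane by construction.
    """
    if pseudocount < 0:
        raise ArgumentError("pseudocount must be >= 0")
    sub = counts.frame[counts.frame["band"] == band]
    if sub.empty:
        raise StructureError(f"no rows for band {band!r}")
    mat = sub.pivot_table(
        index="template_id", columns="lane", values="reads", aggfunc="sum"
    )
    mat = mat + pseudocount
    if (mat == 0).any().any():
        raise NonFiniteValueError(
            "zero read counts with pseudocount 0 make the relative shift "
            "non-finite; set pseudocount > 0"
        )
    control = mat.loc[counts.control_template]
    norm = mat.div(control, axis=1)  # reads_N / reads_601 per lane
    input_norm = norm[counts.input_lane]
    rows = []
    for lane in mat.columns:
        if lane == counts.input_lane:
            continue
        shift = -np.log2(norm[lane] / input_norm)
        for template, value in shift.items():
            if not np.isfinite(value):
                raise NonFiniteValueError(
                    f"non-finite shift for template {template!r} in lane "
                    f"{lane!r}; increase the pseudocount"
                )
            rows.append(
                {"template_id": template, "lane": lane, "relative_shift": float(value)}
            )
    table = pd.DataFrame(rows)
    # exact zero for the control regardless of floating-point round trip
    table.loc[
        table["template_id"] == counts.control_template, "relative_shift"
    ] = 0.0
    return RelativeShiftResult(
        table, band, pseudocount, counts.control_template, counts.input_lane
    )


def summarize_titration(
    result: RelativeShiftResult, lane_order: list[str] | None = None
) -> pd.DataFrame:
    """Per-template maximum shift and monotonicity across a titration series.

    ``lane_order`` gives the concentration ordering (defaults to the order
    lanes appear).  Monotonicity is the Spearman correlation between shift
    and concentration rank (0 when the shifts are flat).
    """
    lanes = lane_order or list(pd.unique(result.table["lane"]))
    if len(lanes) < 2:
        raise InsufficientDataError(
            "titration summary needs at least two non-input lanes"
        )
    rank = {lane: i for i, lane in enumerate(lanes)}
    rows = []
    for template, grp in result.table.groupby("template_id"):
        grp = grp[grp["lane"].isin(rank)].copy()
        grp["rank"] = grp["lane"].map(rank)
        grp = grp.sort_values("rank")
        shifts = grp["relative_shift"].to_numpy()
        imax = int(np.argmax(shifts))
        if np.allclose(shifts, shifts[0]):
            mono = 0.0
        else:
            mono = float(spearmanr(grp["rank"], shifts).statistic)
        rows.append(
            {
                "template_id": template,
                "max_shift": float(shifts[imax]),
                "lane_of_max": grp["lane"].iloc[imax],
                "monotonicity": mono,
            }
        )
    return pd.DataFrame(rows).sort_values(
        "max_shift", ascending=False, ignore_index=True
    )
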