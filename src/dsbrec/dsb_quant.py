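"""Poisson random-breakage quantification of pulsed-field gel band tables.

Gamma irradiation introduces double-strand breaks (DSBs) at random positions,
so the number of breaks per chromosome of molecular weight ``L`` megabases is
Poisson with mean ``r·L`` where ``r`` is the break density in DSBs/Mb.  On a
CHEF gel only full-length (zero-break) molecules run at the native band
position, so the ratio of a band's net intensity in a dose lane to the same
band in the unirradiated control lane estimates the Poisson zero class

    F = P(0 breaks) = exp(-r·L)      =>      N = -ln(F) = r·L.

Plotting N against chromosome size L for every resolvable band yields an
(approximately) straight line through the origin whose slope is the genome-wide
break density in DSBs/Mb; the estimate is independent of the absolute amount
of DNA loaded because only intensity *ratios* enter.  Repair time-courses are
summarised by the ratio of fitted densities at time t to the density
immediately after irradiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Karyotype",
    "GelLaneTable",
    "BreakEstimate",
    "FractionUnbroken",
    "fraction_unbroken",
    "breaks_per_chromosome",
    "fit_dsb_density",
    "quantify_lane",
    "quantify_table",
    "repair_time_course",
    "expected_dsbs",
]

#: CHEF auto-algorithm resolution window (kb): bands outside are excluded
#: from density fits by default.
DEFAULT_SIZE_RANGE_KB = (250.0, 1600.0)


# ---------------------------------------------------------------------------
# Karyotype
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Karyotype:
    """An ordered set of chromosomes the breakage model acts on.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, size_mb)`` pairs; sizes in megabases.
    ploidy
        Copies of each homolog set (1 haploid ... 4 tetraploid).
    replicated
        If True the cell is in G2/M and every chromosome is present as two
        sister chromatids, doubling the molecule count and genome mass.
    """

    chromosomes: tuple
    ploidy: int = 1
    replicated: bool = False

    def __post_init__(self):
        chroms = tuple((str(n), float(s)) for n, s in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        if not chroms:
            raise ValueError("karyotype must contain at least one chromosome")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(s <= 0 for _, s in chroms):
            raise ValueError("chromosome sizes must be strictly positive")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")

    @property
    def names(self) -> tuple:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def sizes_mb(self) -> np.ndarray:
        return np.array([s for _, s in self.chromosomes])

    @property
    def copies_per_chromosome(self) -> int:
        """Full-length molecules per listed chromosome (ploidy x chromatids)."""
        return self.ploidy * (2 if self.replicated else 1)

    @property
    def total_mb(self) -> float:
        """Total genome size in Mb across all copies and chromatids."""
        return float(self.sizes_mb.sum() * self.copies_per_chromosome)

    @classmethod
    def from_tsv(cls, path, *, ploidy: int = 1, replicated: bool = False) -> "Karyotype":
        """Read a two-column TSV ``name<TAB>size_kb`` (header required)."""
        df = pd.read_csv(path, sep="\t")
        missing = {"name", "size_kb"} - set(df.columns)
        if missing:
            raise ValueError(f"karyotype file missing columns: {sorted(missing)}")
        chroms = [(r["name"], float(r["size_kb"]) / 1000.0) for _, r in df.iterrows()]
        return cls(tuple(chroms), ploidy=ploidy, replicated=replicated)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"name": self.names, "size_kb": np.round(self.sizes_mb * 1000).astype(int)}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def yeast(cls, *, ploidy: int = 1, replicated: bool = False) -> "Karyotype":
        """The packaged standard 16-chromosome S. cerevisiae karyotype."""
        from importlib.resources import files

        path = files("dsbrec.data").joinpath("s_cerevisiae_karyotype.tsv")
        with path.open("r") as fh:
            return cls.from_tsv(fh, ploidy=ploidy, replicated=replicated)


# ---------------------------------------------------------------------------
# Gel lane table
# ---------------------------------------------------------------------------

@dataclass
class GelLaneTable:
    """Band-level net intensities for a set of PFGE lanes.

    ``bands`` is tidy (one row per band per lane) with columns
    ``band_id, chromosomes, size_mb, lane_id, intensity, comigrating``;
    ``lanes`` carries lane metadata
    ``lane_id, strain, dose_krad, time_h, is_control``.
    """

    bands: pd.DataFrame
    lanes: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        band_cols = {"band_id", "chromosomes", "size_mb", "lane_id", "intensity"}
        lane_cols = {"lane_id", "strain", "dose_krad", "time_h", "is_control"}
        if missing := band_cols - set(self.bands.columns):
            raise ValueError(f"bands table missing columns: {sorted(missing)}")
        if missing := lane_cols - set(self.lanes.columns):
            raise ValueError(f"lanes table missing columns: {sorted(missing)}")
        if "comigrating" not in self.bands.columns:
            self.bands = self.bands.assign(comigrating=False)
        if self.lanes["lane_id"].duplicated().any():
            dups = self.lanes.loc[self.lanes["lane_id"].duplicated(), "lane_id"]
            raise ValueError(f"duplicate lane ids: {sorted(set(dups))}")
        if (self.bands["intensity"] < 0).any():
            rows = self.bands.index[self.bands["intensity"] < 0].tolist()
            raise ValueError(f"negative intensity at bands rows {rows}")
        for strain, grp in self.lanes.groupby("strain"):
            n_ctrl = int(grp["is_control"].sum())
            if n_ctrl != 1:
                raise ValueError(
                    f"strain {strain!r} has {n_ctrl} control lanes (need exactly 1)"
                )
        # every band_id present in every lane of its strain group
        lane_strain = self.lanes.set_index("lane_id")["strain"]
        merged = self.bands.assign(strain=self.bands["lane_id"].map(lane_strain))
        if merged["strain"].isna().any():
            bad = merged.loc[merged["strain"].isna(), "lane_id"].unique()
            raise ValueError(f"bands reference unknown lanes: {sorted(bad)}")
        for strain, grp in merged.groupby("strain"):
            per_lane = grp.groupby("lane_id")["band_id"].agg(frozenset)
            if per_lane.nunique() != 1:
                raise ValueError(
                    f"strain {strain!r}: lanes do not share an identical band set"
                )

    def control_lane(self, strain: str) -> str:
        grp = self.lanes[(self.lanes["strain"] == strain) & self.lanes["is_control"]]
        return grp["lane_id"].iloc[0]

    def lane_bands(self, lane_id: str) -> pd.DataFrame:
        return self.bands[self.bands["lane_id"] == lane_id]


# ---------------------------------------------------------------------------
# Core estimators
# ---------------------------------------------------------------------------

class FractionUnbroken(NamedTuple):
    """Zero-class fraction with a flag marking a >1 ratio clamped to 1."""

    value: float
    clamped: bool = False

    def __float__(self) -> float:  # allows math.log(float(f)) etc.
        return self.value


def fraction_unbroken(intensity_dose: float, intensity_control: float,
                      *, clamp: bool = True) -> FractionUnbroken:
    """Fraction of chromosomes remaining unbroken after a dose.

    The net intensity of a full-length band in the dose lane divided by the
    net intensity of the corresponding band in the 0-krad control lane.
    Ratios above 1 arise from densitometry noise; by default they are clamped
    to 1 (zero breaks) and flagged rather than dropped.
    """
    if intensity_control <= 0:
        raise ValueError("control intensity must be positive")
    if intensity_dose < 0:
        raise ValueError("dose-lane intensity must be non-negative")
    ratio = float(intensity_dose) / float(intensity_control)
    if ratio > 1 and clamp:
        return FractionUnbroken(1.0, True)
    return FractionUnbroken(ratio, False)


def breaks_per_chromosome(F) -> float:
    """Mean DSBs per chromosome from the Poisson zero class: N = -ln(F).

    ``F`` may be a plain float or a :class:`FractionUnbroken`.  ``F <= 0``
    means the band signal is lost and the break count is unquantifiable; such
    bands must be excluded from fits, so a ValueError is raised rather than
    returning infinity.
    """
    f = float(F)
    if f <= 0:
        raise ValueError("F <= 0: band signal lost, break count unquantifiable")
    if f > 1:
        raise ValueError("F > 1: clamp or investigate before converting to breaks")
    return -math.log(f)


@dataclass
class BreakEstimate:
    """Fitted DSB density for one lane (or an ad-hoc set of (L, N) points).

    ``per_band`` holds the points used (size_mb, fraction_unbroken, clamped,
    breaks); ``excluded`` lists (band_id, reason) pairs left out of the fit.
    """

    per_band: pd.DataFrame
    density: float  # DSBs per Mb (slope)
    stderr: float
    n_bands: int
    excluded: list = field(default_factory=list)
    intercept: float = 0.0
    through_origin: bool = True

    def __post_init__(self):
        if self.n_bands < 2:
            raise ValueError("a density fit needs at least 2 usable bands")


def fit_dsb_density(points: Iterable, *, through_origin: bool = True,
                    band_ids: Sequence | None = None,
                    extra: pd.DataFrame | None = None,
                    excluded: list | None = None) -> BreakEstimate:
    """Least-squares slope of breaks-per-chromosome N against size L (Mb).

    Poisson random breakage forces N = r·L exactly, so the default regression
    is through the origin; ``through_origin=False`` adds a free intercept for
    diagnostics (e.g. a lane-loading mismatch shifts every N by a constant).
    The slope is invariant under a global rescaling of all input intensities
    because only intensity ratios enter N.
    """
    pts = [(float(L), float(N)) for L, N in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 (L, N) points")
    L = np.array([p[0] for p in pts])
    N = np.array([p[1] for p in pts])
    if (L <= 0).any():
        raise ValueError("chromosome sizes must be positive")
    n = len(pts)
    if through_origin:
        slope = float(L @ N / (L @ L))
        resid = N - slope * L
        dof = n - 1
        se = math.sqrt(float(resid @ resid) / dof / float(L @ L)) if dof else float("nan")
        intercept = 0.0
    else:
        X = np.column_stack([np.ones(n), L])
        beta, *_ = np.linalg.lstsq(X, N, rcond=None)
        intercept, slope = float(beta[0]), float(beta[1])
        resid = N - X @ beta
        dof = n - 2
        if dof > 0:
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.inv(X.T @ X)
            se = math.sqrt(cov[1, 1])
        else:
            se = float("nan")
    if extra is not None:
        per_band = extra.copy()
    else:
        per_band = pd.DataFrame({
            "band_id": list(band_ids) if band_ids is not None else list(range(n)),
            "size_mb": L,
            "breaks": N,
        })
    return BreakEstimate(per_band=per_band, density=slope, stderr=se,
                         n_bands=n, excluded=list(excluded or []),
                         intercept=intercept, through_origin=through_origin)


# ---------------------------------------------------------------------------
# Lane-level quantification
# ---------------------------------------------------------------------------

def quantify_lane(table: GelLaneTable, lane_id: str, *,
                  through_origin: bool = True,
                  size_range_kb: tuple = DEFAULT_SIZE_RANGE_KB,
                  include_comigrating: bool = False,
                  clamp: bool = True) -> BreakEstimate:
    """Estimate the DSB density (DSBs/Mb) for one dose/timepoint lane.

    F is always computed against the unirradiated control lane of the same
    strain group.  Bands flagged comigrating or outside the gel's resolution
    window are excluded by default; bands whose signal is lost (F = 0) are
    excluded with reason ``signal_lost``.
    """
    lane_meta = table.lanes[table.lanes["lane_id"] == lane_id]
    if lane_meta.empty:
        raise ValueError(f"unknown lane {lane_id!r}")
    strain = lane_meta["strain"].iloc[0]
    control_id = table.control_lane(strain)
    dose = table.lane_bands(lane_id).set_index("band_id")
    ctrl = table.lane_bands(control_id).set_index("band_id")

    lo_mb, hi_mb = size_range_kb[0] / 1000.0, size_range_kb[1] / 1000.0
    rows, excluded = [], []
    for band_id, row in dose.iterrows():
        L = row["size_mb"]
        if bool(row.get("comigrating", False)) and not include_comigrating:
            excluded.append((band_id, "comigrating"))
            continue
        if not (lo_mb <= L <= hi_mb):
            excluded.append((band_id, "outside_resolution_window"))
            continue
        c = ctrl.loc[band_id, "intensity"]
        if c <= 0:
            excluded.append((band_id, "control_signal_lost"))
            continue
        F = fraction_unbroken(row["intensity"], c, clamp=clamp)
        if F.value <= 0:
            excluded.append((band_id, "signal_lost"))
            continue
        rows.append({"band_id": band_id, "size_mb": L,
                     "fraction_unbroken": F.value, "clamped": F.clamped,
                     "breaks": breaks_per_chromosome(F)})
    if len(rows) < 2:
        raise ValueError(
            f"lane {lane_id!r}: only {len(rows)} usable bands after exclusions"
        )
    per_band = pd.DataFrame(rows)
    return fit_dsb_density(per_band[["size_mb", "breaks"]].to_numpy(),
                           through_origin=through_origin,
                           extra=per_band, excluded=excluded)


def quantify_table(table: GelLaneTable, **kwargs) -> dict:
    """Quantify every non-control lane; returns {lane_id: BreakEstimate}."""
    out = {}
    for _, lane in table.lanes[~table.lanes["is_control"]].iterrows():
        out[lane["lane_id"]] = quantify_lane(table, lane["lane_id"], **kwargs)
    return out


def repair_time_course(table: GelLaneTable, strain: str | None = None, *,
                       dose: float | None = None, **fit_kwargs) -> pd.DataFrame:
    """Per-timepoint break density and repaired/unrepaired fractions.

    fraction_unrepaired(t) = density(t) / density(0), where t = 0 is the lane
    taken immediately after irradiation (before repair).  Densities come from
    :func:`quantify_lane` so information is pooled across bands.
    """
    lanes = table.lanes[~table.lanes["is_control"]]
    if strain is not None:
        lanes = lanes[lanes["strain"] == strain]
    if dose is not None:
        lanes = lanes[lanes["dose_krad"] == dose]
    if lanes.empty:
        raise ValueError("no irradiated lanes match the requested strain/dose")
    if not (lanes["time_h"] == 0).any():
        raise ValueError("repair time-course requires a t=0 post-irradiation lane")
    lanes = lanes.sort_values("time_h")
    records = []
    d0 = None
    for _, lane in lanes.iterrows():
        est = quantify_lane(table, lane["lane_id"], **fit_kwargs)
        if lane["time_h"] == 0:
            d0 = est.density
        records.append({"lane_id": lane["lane_id"], "strain": lane["strain"],
                        "dose_krad": lane["dose_krad"], "time_h": lane["time_h"],
                        "density": est.density, "stderr": est.stderr})
    df = pd.DataFrame(records)
    if d0 is None or d0 <= 0:
        raise ValueError("t=0 density is zero; repaired fraction undefined")
    df["fraction_unrepaired"] = df["density"] / d0
    df["fraction_repaired"] = 1.0 - df["fraction_unrepaired"]
    return df


# ---------------------------------------------------------------------------
# Expected genome-wide break burden
# ---------------------------------------------------------------------------

def expected_dsbs(efficiency_kappa: float, dose: float, karyotype: Karyotype) -> float:
    """Expected genome-wide DSBs per cell: kappa x dose x genome megabases.

    The genome size is ploidy- and replication-aware: a G2/M-arrested
    tetraploid counts 8 haploid genome equivalents.
    """
    if efficiency_kappa < 0 or dose < 0:
        raise ValueError("efficiency and dose must be non-negative")
    return efficiency_kappa * dose * karyotype.total_mb
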