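"""Readers and writers for long-format abundance tables and component tables.

The canonical input is a CSV with columns site, plot, year, species,
abundance (biomass in g/m^2 or percent cover; the two are treated
identically because every statistic is a unitless ratio, scale-invariant by
construction — a ``units`` field is carried for provenance only).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .analysis import ComponentRecord, records_frame
from .community import CommunityMatrix
from .exceptions import InputError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("site", "plot", "year", "species", "abundance")


@dataclass
class Dataset:
    """Community matrices grouped by site, with provenance metadata."""

    sites: dict[str, list[CommunityMatrix]]
    metadata: dict = field(default_factory=dict)

    def plots(self) -> list[CommunityMatrix]:
        return [p for plots in self.sites.values() for p in plots]

    def __len__(self) -> int:
        return sum(len(v) for v in self.sites.values())


def read_long_table(path, units: str = "abundance",
                    align_site_years: bool = True,
                    allow_negative: bool = False) -> Dataset:
    """Read a long-format abundance CSV into a :class:`Dataset`.

    Duplicate (plot, year, species) rows are summed (logged).  Species absent
    in a year are filled with 0.  Within a site, plots are restricted to
    their common years (inner join, logged) when ``align_site_years`` is
    set — the surrogate constructions require identical time coverage.
    Negative abundances are rejected unless ``allow_negative`` is set (the
    untruncated Gaussian simulator can produce them; every statistic is a
    moment ratio and remains well defined).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {', '.join(missing)}")
    year = pd.to_numeric(df["year"], errors="coerce")
    if year.isna().any():
        bad = int(df.index[year.isna()][0]) + 2  # header is line 1
        raise InputError(f"{path}: non-numeric year at line {bad}")
    df = df.assign(year=year)
    ab = pd.to_numeric(df["abundance"], errors="coerce")
    if ab.isna().any():
        bad = int(df.index[ab.isna()][0]) + 2
        raise InputError(f"{path}: non-numeric abundance at line {bad}")
    if not allow_negative and (ab < 0).any():
        bad = int(df.index[ab < 0][0]) + 2
        raise InputError(f"{path}: negative abundance at line {bad}")
    df = df.assign(abundance=ab)

    dup = df.duplicated(subset=["site", "plot", "year", "species"])
    if dup.any():
        logger.warning("%s: summed %d duplicated (plot, year, species) row(s)",
                       path, int(dup.sum()))

    sites: dict[str, list[CommunityMatrix]] = {}
    for (site_id, plot_id), sub in df.groupby(["site", "plot"], sort=True):
        cm = CommunityMatrix.from_frame(sub, plot_id=str(plot_id),
                                        site_id=str(site_id), units=units)
        sites.setdefault(str(site_id), []).append(cm)

    if align_site_years:
        for site_id, plots in sites.items():
            common = set(plots[0].times)
            for p in plots[1:]:
                common &= set(p.times)
            if not all(set(p.times) == common for p in plots):
                logger.info("site %s: restricting plots to %d common year(s)",
                            site_id, len(common))
                aligned = []
                for p in plots:
                    keep = [t in common for t in p.times]
                    aligned.append(CommunityMatrix(
                        values=p.values[np.asarray(keep)],
                        species=p.species,
                        times=[t for t in p.times if t in common],
                        plot_id=p.plot_id, site_id=p.site_id, units=p.units,
                    ))
                sites[site_id] = aligned
    return Dataset(sites=sites, metadata={"source": str(path), "units": units})


def read_monocultures(path, allow_negative: bool = False
                      ) -> dict[str, dict[str, list[np.ndarray]]]:
    """Read monoculture plots (single-species plots) from a long-format CSV.

    Returns a map site -> species -> list of time series.  A plot containing
    more than one species is rejected.
    """
    ds = read_long_table(path, align_site_years=True, allow_negative=allow_negative)
    out: dict[str, dict[str, list[np.ndarray]]] = {}
    for site_id, plots in ds.sites.items():
        per_species: dict[str, list[np.ndarray]] = {}
        for p in plots:
            if p.n_species != 1:
                raise InputError(
                    f"{path}: plot {p.plot_id!r} has {p.n_species} species; "
                    "monoculture plots must contain exactly one"
                )
            per_species.setdefault(p.species[0], []).append(p.values[:, 0])
        out[site_id] = per_species
    return out


def write_long_table(plots: Iterable[CommunityMatrix], path) -> None:
    """Write plots back to the canonical long-format CSV."""
    frames = [p.to_frame() for p in plots]
    if not frames:
        raise InputError("no plots to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_components(records: Sequence[ComponentRecord], path,
                     metadata: Mapping | None = None) -> None:
    """Write component records as tidy CSV plus a JSON mirror with metadata.

    The JSON file (same stem, ``.json`` suffix) carries the full records and
    provenance (software version, seeds, filters) for reproducibility.
    """
    if not records:
        raise InputError("no records to write")
    frame = records_frame(records)
    frame.to_csv(path, index=False)
    meta = {"commstab_version": __version__}
    if metadata:
        meta.update(metadata)
    payload = {
        "metadata": meta,
        "records": frame.to_dict(orient="records"),
    }
    json_path = str(path)
    json_path = json_path[: -len(".csv")] + ".json" if json_path.endswith(".csv") \
        else json_path + ".json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
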