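"""Per-plate Z-score normalization and assembly of the reagent profile matrix.

Raw assay readings are normalized within each 384-well plate as
``Z = (x - mu) / sigma``, where ``mu`` and ``sigma`` are the mean and standard
deviation of the plate's sample wells.  Empty perimeter wells and control
wells carry no reagent and are excluded both from the statistics and from the
output (focused sub-library plates leave the outer perimeter empty to blunt
edge effects, so including them would shift every score).

Normalized screens are then stacked into a reagent x screen/replicate matrix
— the substrate for cross-screen clustering and for replicate-based hit
calling.  Missing entries (a reagent absent from a screen) stay missing; they
are never imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DegeneratePlateError",
    "PLATE_COLUMNS",
    "compute_plate_zscores",
    "normalize_plates",
    "assemble_profile_matrix",
]

#: Column schema of a plate-reading table.
PLATE_COLUMNS = [
    "screen_id",
    "replicate",
    "plate_id",
    "row",
    "col",
    "well_role",
    "reagent_id",
    "value",
]

WELL_ROLES = frozenset({"sample", "empty", "control"})


class DegeneratePlateError(ValueError):
    """Raised when a plate cannot be Z-normalized (too few sample wells or zero spread)."""


def compute_plate_zscores(
    plate: pd.DataFrame,
    ddof: int = 1,
    include_controls: bool = False,
) -> pd.DataFrame:
    """Z-score the sample wells of a single plate.

    Parameters
    ----------
    plate
        Readings for one plate (``PLATE_COLUMNS`` schema, or at least
        ``well_role``, ``reagent_id``, ``value``).
    ddof
        Delta degrees of freedom for sigma.  Default 1 (sample SD); 0 gives
        the population SD.
    include_controls
        If True, control wells enter mu and sigma (they still receive no Z).
        Whether the original plate statistics excluded controls is not
        documented for historical screens, so both conventions are supported.

    Returns
    -------
    DataFrame
        The sample-well rows with an added ``z`` column.

    Raises
    ------
    DegeneratePlateError
        Fewer than 3 sample wells, or zero spread among the statistic wells.
    """
    is_sample = plate["well_role"] == "sample"
    samples = plate[is_sample]
    if len(samples) < 3:
        raise DegeneratePlateError(
            f"plate needs >= 3 sample wells to normalize, got {len(samples)}"
        )
    stat_mask = is_sample | (plate["well_role"] == "control") if include_controls else is_sample
    values = plate.loc[stat_mask, "value"].to_numpy(dtype=float)
    mu = values.mean()
    sigma = values.std(ddof=ddof)
    if sigma == 0.0 or not np.isfinite(sigma):
        raise DegeneratePlateError("zero spread among plate wells; Z-score undefined")
    out = samples.copy()
    out["z"] = (samples["value"].to_numpy(dtype=float) - mu) / sigma
    return out


def normalize_plates(
    readings: pd.DataFrame,
    ddof: int = 1,
    include_controls: bool = False,
) -> pd.DataFrame:
    """Z-score every plate of a multi-screen reading table.

    Plates are normalized independently within each (screen, replicate,
    plate) group.  Returns sample-well rows with a ``z`` column.
    """
    missing = [c for c in PLATE_COLUMNS if c not in readings.columns]
    if missing:
        raise ValueError(f"plate table lacks columns: {missing}")
    parts = []
    for _, plate in readings.groupby(["screen_id", "replicate", "plate_id"], sort=False):
        parts.append(compute_plate_zscores(plate, ddof=ddof, include_controls=include_controls))
    return pd.concat(parts, ignore_index=True)


def assemble_profile_matrix(
    normalized: pd.DataFrame,
    column_by: tuple[str, ...] = ("screen_id", "replicate"),
) -> pd.DataFrame:
    """Stack normalized screens into a reagent x screen/replicate Z matrix.

    Rows are the union of reagents over all screens; entries where a reagent
    was absent from a screen are NaN.  Column order follows first appearance
    in the input.  Columns are named ``screen`` for single-replicate screens
    and ``screen:replicate`` otherwise.

    Raises
    ------
    ValueError
        If a reagent occurs more than once within one screen replicate.
    """
    df = normalized
    if "z" not in df.columns:
        raise ValueError("expected a normalized table with a 'z' column")
    key = df[list(column_by)].astype(str).agg(":".join, axis=1)
    # collapse "screen:rep" to "screen" when the screen has a single replicate
    if "replicate" in column_by:
        n_reps = df.groupby("screen_id")["replicate"].nunique()
        single = set(n_reps[n_reps == 1].index.astype(str))
        screen = df["screen_id"].astype(str)
        key = key.where(~screen.isin(single), screen)
    dup = df.assign(_col=key).duplicated(subset=["reagent_id", "_col"], keep=False)
    if dup.any():
        bad = df.loc[dup, "reagent_id"].iloc[0]
        raise ValueError(f"reagent {bad!r} appears more than once in one screen replicate")
    wide = (
        df.assign(_col=key)
        .pivot(index="reagent_id", columns="_col", values="z")
        .reindex(columns=key.unique())
    )
    wide.columns.name = None
    wide.index.name = "reagent_id"
    return wide
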