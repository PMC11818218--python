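"""Relative quantification of modification-site intensities.

Raw site intensities are centralized per site: each value is divided by
the mean of that site's observed intensities across all samples, giving
relative values R with mean 1 on complete rows. Optionally the site-level
relative values are divided cell-wise by the parent protein's relative
values, removing protein-abundance effects so that the remaining signal
reflects changes in modification stoichiometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ProteinQuantTable, SiteIntensityTable

log = logging.getLogger(__name__)


@dataclass
class RelativeQuantMatrix:
    """Centralized (optionally protein-corrected) relative values.

    ``values`` is a row-id x sample matrix of positive floats with nan for
    missing cells. ``uncorrected`` marks cells where protein correction was
    requested but the parent protein value was unavailable, so the raw
    relative value was kept.
    """

    values: pd.DataFrame
    corrected: bool = False
    uncorrected: pd.DataFrame | None = None
    n_dropped: int = 0
    dropped_ids: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def centralize(
    table: SiteIntensityTable | ProteinQuantTable | pd.DataFrame,
    min_observed: int = 2,
) -> RelativeQuantMatrix:
    """Transform intensities I into relative values R = I / row mean.

    The mean is taken over a row's observed (non-missing) cells only.
    Rows with fewer than ``min_observed`` observed values carry no usable
    relative information and are dropped with a warning count.
    """
    if isinstance(table, (SiteIntensityTable, ProteinQuantTable)):
        inten = table.intensities
    else:
        inten = table
    n_obs = inten.notna().sum(axis=1)
    keep = n_obs >= min_observed
    dropped = list(inten.index[~keep])
    if dropped:
        log.warning(
            "centralize: dropped %d row(s) with < %d observed values",
            len(dropped), min_observed,
        )
    inten = inten.loc[keep]
    means = inten.mean(axis=1, skipna=True)
    values = inten.div(means, axis=0)
    return RelativeQuantMatrix(
        values=values, corrected=False,
        n_dropped=len(dropped), dropped_ids=dropped,
    )


def correct_by_protein(
    site_R: RelativeQuantMatrix,
    protein_R: RelativeQuantMatrix,
    site_table: SiteIntensityTable,
) -> RelativeQuantMatrix:
    """Divide site relative values by the parent protein's relative values.

    The division is cell-wise: where the parent protein is absent from the
    protein matrix, or its value in a given sample is missing, the site's
    relative value is kept unchanged for that cell and the cell is flagged
    in ``uncorrected`` — a single protein dropout does not discard the site.
    """
    parents = site_table.sites["protein_id"].reindex(site_R.values.index)
    samples = site_R.samples
    prot = protein_R.values.reindex(index=parents.to_numpy(), columns=samples)
    prot.index = site_R.values.index
    denom = prot.to_numpy(dtype=float)
    site = site_R.values.to_numpy(dtype=float)

    have_prot = np.isfinite(denom)
    out = np.where(have_prot, site / np.where(have_prot, denom, 1.0), site)
    uncorrected = ~have_prot & np.isfinite(site)
    n_flagged = int(uncorrected.sum())
    if n_flagged:
        log.info("protein correction: %d cell(s) kept uncorrected", n_flagged)
    return RelativeQuantMatrix(
        values=pd.DataFrame(out, index=site_R.values.index, columns=samples),
        corrected=True,
        uncorrected=pd.DataFrame(
            uncorrected, index=site_R.values.index, columns=samples
        ),
        n_dropped=site_R.n_dropped,
        dropped_ids=list(site_R.dropped_ids),
    )


def write_relquant(matrix: RelativeQuantMatrix, path) -> None:
    """Write a relative-quant matrix as TSV with a per-row flags column."""
    out = matrix.values.copy()
    out.index.name = "site_id"
    if matrix.uncorrected is not None:
        flagged = matrix.uncorrected.any(axis=1)
        out["flags"] = np.where(flagged, "uncorrected_cells", "")
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")
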