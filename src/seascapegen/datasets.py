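"""Packaged reference tables.

``irish_sites()`` returns the 26-site Irish blue-mussel sampling campaign
metadata (site code, location, region, WGS84 coordinates, sample size and
stock/habitat type).  The 26 sample sizes sum to 781 screened individuals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genotypes import SiteTable

__all__ = ["irish_sites", "irish_site_table"]


def irish_sites() -> pd.DataFrame:
    """The Irish sampling-campaign site table as a DataFrame."""
    with resources.files("seascapegen.data").joinpath("irish_sites.csv").open() as fh:
        return pd.read_csv(fh)


def irish_site_table() -> SiteTable:
    """The same table wrapped as a :class:`~seascapegen.genotypes.SiteTable`."""
    return SiteTable(irish_sites())
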