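"""Published annual inputs for the irrigated-alfalfa study site.

The bundled table holds the per-site-year measured inputs (annual chamber
N2O/CH4/CO2 mass fluxes and eddy-covariance NEE/R_eco/GPP) from which the
budget arithmetic (GWP conversion, total CO2e, N-mass conversion, harvest
accounting) is recomputed at run time; none of the derived columns are
stored.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: mean annual harvested yield, g C m-2 y-1 and g CO2 m-2 y-1 (the two
#: published figures are kept separate and never interconverted)
HARVEST_C_G_M2_Y = 595.0
HARVEST_CO2_G_M2_Y = 2072.0


def load_annual_inputs() -> pd.DataFrame:
    """Measured annual inputs per site year (last row aggregates all years)."""
    with resources.files("chamberflux.data").joinpath("site_annual_inputs.csv").open() as fh:
        return pd.read_csv(fh)
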