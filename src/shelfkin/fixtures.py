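"""Packaged study tables: the intermediate-moisture-longan storage trial.

The package ships the printed tables of a 24-week accelerated storage study
of intermediate moisture longan (IML, osmotically dehydrated to a_w ≈ 0.6)
in three packaging types — aluminium-laminated bags flushed with nitrogen
(``al_bag_n2``), the same bags air-packed (``al_bag_air``), and clear
polyamide bags (``clear_plastic``) — stored at 4, 25, 35 and 45 °C:

========================  =====================================================
``table1_microbial``      total bacterial / yeast-and-mould counts (cfu/g),
                          with "<2.5e-1" detection-limit records
``table2_sensory``        9-point hedonic panel means ± sd (N = 50) for
                          overall, colour and flavour acceptance, censored
                          once the product was rejected
``table3_lstar_k``        printed zero/first-order rate constants and R² for
                          the instrumental lightness L*
``table4_color_k``        printed rate constants and R² for the colour
                          acceptance score
``table5_shelf_life``     actual vs model-predicted shelf life (weeks), with
                          open bounds (">24", "<3")
``baselines``             week-0 hedonic means (overall 6.2, colour 6.3,
                          flavour 6.0)
========================  =====================================================

Cells are transcribed verbatim, including two rate-constant entries whose
printed scale is inconsistent with their neighbours (``note`` column
``scale_anomaly``) and one that conflicts with the value the study's
conclusions quote for the same condition (``conflicts_conclusions``).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .dataset import StudyDataset, load_quality_csv
from .errors import FixtureLookupError

__all__ = ["FIXTURE_NAMES", "builtin_fixture", "fixture_path", "printed_rate"]

FIXTURE_NAMES = (
    "table1_microbial",
    "table2_sensory",
    "table3_lstar_k",
    "table4_color_k",
    "table5_shelf_life",
    "baselines",
)

_FILES = {name: f"{name}.csv" for name in FIXTURE_NAMES}

#: Fixtures in the tidy observation schema (loadable as a StudyDataset).
_DATASET_FIXTURES = {"table1_microbial", "table2_sensory"}


def fixture_path(name: str):
    """Path-like handle to a packaged fixture CSV."""
    if name not in _FILES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return resources.files("shelfkin.data").joinpath(_FILES[name])


def builtin_fixture(name: str) -> StudyDataset | pd.DataFrame:
    """Return a packaged table.

    ``table1_microbial`` and ``table2_sensory`` come back as a
    :class:`~shelfkin.dataset.StudyDataset` (the sensory dataset carries the
    week-0 baselines); the rate-constant and shelf-life tables and the
    baselines come back as :class:`pandas.DataFrame`.
    """
    path = fixture_path(name)
    with resources.as_file(path) as p:
        if name in _DATASET_FIXTURES:
            dataset = load_quality_csv(p)
            if name == "table2_sensory":
                base = pd.read_csv(fixture_path("baselines"))
                dataset.baseline = dict(zip(base["attribute"], base["value"]))
            return dataset
        return pd.read_csv(p, keep_default_na=False)


def printed_rate(
    table: pd.DataFrame, order: str, packaging: str, temperature_c: float
) -> float:
    """Look up one printed rate constant in a table3/table4 frame."""
    rows = table[
        (table["order"] == order)
        & (table["packaging"] == packaging)
        & (table["temperature_c"] == temperature_c)
    ]
    if len(rows) != 1:
        raise FixtureLookupError(
            f"no unique printed k for ({order}, {packaging}, {temperature_c} °C)"
        )
    return float(rows["k"].iloc[0])
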