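"""Shared setup for the analysis drivers: one deterministic campaign.

Every driver analyses the same synthetic 9-lake, 18-month, 3-replicate
campaign generated under the default eutrophication gradient (seed below),
so their outputs are mutually consistent and reproducible.
"""

import pathlib

from limnotraj.synthetic import SyntheticConfig, generate_lake_series

CAMPAIGN_SEED = 20240601
RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"

_cache = {}


def campaign():
    """(counts, metadata, chla, ground truth) for the shared campaign."""
    if "campaign" not in _cache:
        _cache["campaign"] = generate_lake_series(
            SyntheticConfig(), seed=CAMPAIGN_SEED
        )
    return _cache["campaign"]


def outdir(name: str) -> pathlib.Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
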