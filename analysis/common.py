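"""Shared configuration for the numbered analysis scripts.

The campaign analyzed here is the desk-scale emulation of the field
deployment: four site years (Jan 27, 2017 - Jan 26, 2021) at roughly ten
closures per day from one cycling chamber, 0.2 Hz analyzer sampling.
Scripts regenerate the campaign from the seed where needed (generation is
deterministic and cheap) instead of shuttling multi-million-row trace
files between stages.
"""

from pathlib import Path

from chamberflux.synthetic import CampaignConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20170127


def campaign_config(seed: int = SEED) -> CampaignConfig:
    return CampaignConfig(
        seed=seed,
        n_chambers=1,
        idle_minutes_per_cycle=132.5,
        start_date="2017-01-27",
        end_date="2021-01-27",
        sample_hz=0.2,
    )
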