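"""Bundled example data."""

from importlib import resources

from .survey import SummaryTable, read_summary_table

__all__ = ["lvhua_macroalgae"]


def lvhua_macroalgae() -> SummaryTable:
    """Published per-species summary of an intertidal macroalgae survey.

    Fifteen species scored by the Binary Method on a rocky-shore transect of
    50 L-quadrats × 4 S-quadrats (Lvhua Island, East China Sea, August 2020):
    occurrence frequency p, community-relative residual ε, and heterogeneity
    index δ for each species.  Frequencies range from a single occupied
    S-quadrat (p = 0.005) to near-ubiquitous Ulva australis (p = 0.79).
    """
    ref = resources.files("quadlaw").joinpath("data/lvhua_macroalgae.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return read_summary_table(fh, sep=",")
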