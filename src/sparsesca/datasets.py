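"""Bundled example data."""

from __future__ import annotations

from importlib import resources

from .io import MultiblockData, read_blocks

__all__ = ["load_herring"]


def load_herring() -> MultiblockData:
    """Two-block ripening study of 21 salted herring samples.

    Block ``ChemPhy`` holds 10 physical/chemical measurements, block
    ``Sensory`` 10 sensory ratings of the same samples.  Raw (unprocessed)
    values are returned.
    """
    pkg = resources.files(__package__) / "data"
    with resources.as_file(pkg / "herring_chemphy.csv") as cp, resources.as_file(
        pkg / "herring_sensory.csv"
    ) as se:
        return read_blocks([str(cp), str(se)], block_names=["ChemPhy", "Sensory"])
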