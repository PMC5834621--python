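"""Accessors for packaged parameter sets and reference tables."""

from importlib.resources import files
from pathlib import Path


def packaged_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(files(__package__) / name))


def toy_forcefield():
    """The packaged toy force field (kJ/mol native config)."""
    from ..forcefield import load_parameters
    return load_parameters(packaged_path("toy_forcefield.yaml"), "native-config")


def charmm27_forcefield():
    """The transcribed modified-CHARMM27 hydrocarbon parameter set."""
    from ..forcefield import load_parameters
    return load_parameters(packaged_path("charmm27_hydrocarbon.yaml"), "native-config")


def table8():
    """Published end-to-end distance table as a pandas DataFrame."""
    import pandas as pd
    return pd.read_csv(packaged_path("table8.tsv"), sep="\t")
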