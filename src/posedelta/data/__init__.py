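"""Packaged ligand structure fixtures."""

from importlib import resources
from pathlib import Path

LIGANDS = (
    "pomolic_acid",
    "hederagenin",
    "caulophyllogenin",
    "betulinic_acid",
    "rosiglitazone",
)


def ligand_sdf_path(name: str) -> Path:
    """Filesystem path of a packaged ligand SDF fixture."""
    if name not in LIGANDS:
        raise KeyError(f"unknown ligand {name!r}; available: {LIGANDS}")
    return Path(resources.files(__package__) / "ligands" / f"{name}.sdf")
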