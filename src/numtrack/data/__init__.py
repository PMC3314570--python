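"""Bundled reference data.

``rpnumts_mito_region.bed`` holds the published RPNumtS (chimpanzee,
panTro2) mitochondrion-projected track entries overlapping the mitochondrial
region 1006-1771 used in the primer-selection worked example — the standard
co-amplification screening demonstration for this catalogue.
"""

from importlib import resources

from ..tracks import TrackRecord, read_bed

__all__ = ["load_chimp_mito_track"]

# panTro2 chimpanzee mitochondrial genome length (NC_001643)
CHIMP_MTDNA_LENGTH = 16554


def load_chimp_mito_track() -> list[TrackRecord]:
    """The chimpanzee mitochondrion-projected NumtS track subset (BED6)."""
    path = resources.files(__package__) / "rpnumts_mito_region.bed"
    with resources.as_file(path) as p:
        return read_bed(p)
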