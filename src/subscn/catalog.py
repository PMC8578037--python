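"""The subcortical ROI catalog.

One hundred regions of interest: per hemisphere 4 basal-ganglia structures
(caudate, putamen, nucleus accumbens, pallidum), 9 amygdaloid nuclei,
12 hippocampal subfields and 25 thalamic nuclei.  The catalog ships as an
editable TSV (``data/roi_catalog.tsv``) using FreeSurfer-style names; the
cardinality per structure group is enforced on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["ROICatalog", "CatalogError", "load_catalog", "default_catalog"]

HEMISPHERES = ("L", "R")
STRUCTURE_GROUPS = ("basal_ganglia", "amygdala", "hippocampus", "thalamus")

#: required ROI count per (hemisphere, structure_group)
_EXPECTED_COUNTS = {
    "basal_ganglia": 4,
    "amygdala": 9,
    "hippocampus": 12,
    "thalamus": 25,
}


class CatalogError(ValueError):
    """Raised when a catalog file violates the cardinality or naming rules."""


@dataclass(frozen=True)
class ROICatalog:
    """Ordered list of (roi_name, hemisphere, structure_group) entries."""

    entries: tuple[tuple[str, str, str], ...] = field(repr=False)

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            raise CatalogError("duplicate ROI names in catalog")
        for hemi in HEMISPHERES:
            for group, expected in _EXPECTED_COUNTS.items():
                n = sum(1 for _, h, g in self.entries if h == hemi and g == group)
                if n != expected:
                    raise CatalogError(
                        f"hemisphere {hemi}, group {group}: expected "
                        f"{expected} ROIs, found {n}"
                    )
        if len(self.entries) != 100:
            raise CatalogError(f"catalog must have 100 entries, found {len(self.entries)}")

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def hemisphere(self, roi_name: str) -> str:
        return dict((n, h) for n, h, _ in self.entries)[roi_name]

    def structure_group(self, roi_name: str) -> str:
        return dict((n, g) for n, _, g in self.entries)[roi_name]

    def subset(self, names: list[str]) -> list[str]:
        """Validate that ``names`` are catalog members; return them in catalog order."""
        unknown = sorted(set(names) - set(self.names))
        if unknown:
            raise CatalogError(f"not in catalog: {', '.join(unknown)}")
        keep = set(names)
        return [n for n in self.names if n in keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["roi_name", "hemisphere", "structure_group"])


def load_catalog(path: str | Path) -> ROICatalog:
    """Load a catalog TSV with columns roi_name, hemisphere, structure_group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"roi_name", "hemisphere", "structure_group"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"catalog file missing columns: {sorted(missing)}")
    bad_hemi = set(df["hemisphere"]) - set(HEMISPHERES)
    if bad_hemi:
        raise CatalogError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
    bad_group = set(df["structure_group"]) - set(STRUCTURE_GROUPS)
    if bad_group:
        raise CatalogError(f"unknown structure groups: {sorted(bad_group)}")
    entries = tuple(
        (str(r.roi_name), str(r.hemisphere), str(r.structure_group))
        for r in df.itertuples(index=False)
    )
    return ROICatalog(entries)


def default_catalog() -> ROICatalog:
    """The shipped 100-ROI catalog."""
    ref = resources.files("subscn.data").joinpath("roi_catalog.tsv")
    with resources.as_file(ref) as path:
        return load_catalog(path)
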