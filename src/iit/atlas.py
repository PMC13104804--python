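"""Region atlas: per-region cohort mean volumes and printed atrophy percentages.

The packaged atlas lists 84 neuroanatomical regions (FreeSurfer-style
parcellation: cortical and subcortical gray matter, white matter,
ventricles, CSF) with the mean volume of each region in the healthy
control (CN), Parkinson's disease (PD) and Alzheimer's disease (AD)
cohorts, in units of 10^3 mm^3, plus the PD/AD atrophy percentages
relative to the CN baseline.  The atlas parameterizes the synthetic
cohort generator and serves as the reference for the atrophy-percentage
arithmetic.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Union

__all__ = ["RegionRecord", "AtlasParseError", "load_region_atlas", "BUILTIN"]

BUILTIN = "builtin"

_HEMISPHERES = frozenset({"LH", "RH", "midline", "global"})
_COLUMNS = ("region", "hemisphere", "cn_mean", "pd_mean", "ad_mean", "pda", "ada")


class AtlasParseError(ValueError):
    """Raised when an atlas fixture cannot be parsed or fails validation."""


@dataclass(frozen=True)
class RegionRecord:
    """One atlas region: cohort mean volumes and printed atrophy percentages.

    Volumes are in 10^3 mm^3; ``pda`` / ``ada`` are the printed percentage
    atrophy of the PD / AD cohort relative to CN (negative = expansion).
    """

    region_name: str
    hemisphere: str
    cn_mean: float
    pd_mean: float
    ad_mean: float
    pda_printed: float
    ada_printed: float

    def __post_init__(self) -> None:
        if self.hemisphere not in _HEMISPHERES:
            raise AtlasParseError(
                f"region {self.region_name!r}: unknown hemisphere {self.hemisphere!r}"
            )
        for field in ("cn_mean", "pd_mean", "ad_mean"):
            if not getattr(self, field) > 0:
                raise AtlasParseError(
                    f"region {self.region_name!r}: {field} must be strictly positive"
                )


def _builtin_path() -> Path:
    return Path(
        importlib.resources.files("iit").joinpath("data", "region_atlas.tsv")  # type: ignore[arg-type]
    )


def load_region_atlas(fixture_path: Union[str, Path] = BUILTIN) -> list[RegionRecord]:
    """Load a region atlas from a TSV fixture.

    Parameters
    ----------
    fixture_path
        Path to a TSV file with columns
        ``region, hemisphere, cn_mean, pd_mean, ad_mean, pda, ada``,
        or the string ``"builtin"`` for the packaged 84-region atlas.

    Returns
    -------
    list of RegionRecord, in file order.  The atlas size is data-driven:
    a truncated fixture yields fewer records without error.

    Raises
    ------
    AtlasParseError
        On a malformed row (named by its 1-based line number), a duplicate
        region name, or a non-positive mean volume.
    """
    path = _builtin_path() if fixture_path == BUILTIN else Path(fixture_path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise AtlasParseError(f"{path}: empty atlas fixture")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != _COLUMNS:
        raise AtlasParseError(
            f"{path}: expected columns {list(_COLUMNS)}, found {list(header)}"
        )
    records: list[RegionRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(_COLUMNS):
            raise AtlasParseError(
                f"{path}: line {lineno}: expected {len(_COLUMNS)} fields, got {len(parts)}"
            )
        name = parts[0].strip()
        if name in seen:
            raise AtlasParseError(f"{path}: line {lineno}: duplicate region name {name!r}")
        seen.add(name)
        try:
            numbers = [float(x) for x in parts[2:]]
        except ValueError as exc:
            raise AtlasParseError(f"{path}: line {lineno}: non-numeric field ({exc})") from exc
        records.append(
            RegionRecord(
                region_name=name,
                hemisphere=parts[1].strip(),
                cn_mean=numbers[0],
                pd_mean=numbers[1],
                ad_mean=numbers[2],
                pda_printed=numbers[3],
                ada_printed=numbers[4],
            )
        )
    return records
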