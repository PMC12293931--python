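"""Per-target configuration tables pairing amplicons with recognition sequences.

For a target guide g_i the table has one on-target row (g_i's own amplicon
with the designed guide in the gRNA cell) and one off-target row for every
retained candidate site in each sibling amplicon, with the putative
recognition sequence in the gRNA cell.  This is the hand-off format for
per-site quantification, either by this package's quantifier or by an
external amplicon analyzer that accepts (site name, amplicon reference, gRNA)
triples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from ._util import revcomp
from .enumeration import EnumerationResult
from .family import GeneFamily

#: column headers for the minimal external dialect, following the public
#: convention of amplicon-analysis config files; remappable via header_map.
CRISPECTOR_HEADERS = {"site_name": "SiteName", "amplicon": "AmpliconReference", "grna": "gRNA"}

NATIVE_COLUMNS = ["site_name", "amplicon_name", "amplicon_sequence", "grna", "role", "source_guide"]


@dataclass(frozen=True)
class ConfigRow:
    site_name: str
    amplicon_name: str
    amplicon_sequence: str
    grna: str
    role: str  # {"on_target", "off_target"}
    source_guide: str

    def __post_init__(self):
        if len(self.grna) != 20:
            raise ValueError(f"row {self.site_name!r}: gRNA cell must be 20 nt")
        if self.role not in ("on_target", "off_target"):
            raise ValueError(f"row {self.site_name!r}: bad role {self.role!r}")
        if self.grna not in self.amplicon_sequence and revcomp(self.grna) not in self.amplicon_sequence:
            raise ValueError(
                f"row {self.site_name!r}: recognition sequence absent from amplicon "
                f"{self.amplicon_name!r} on both strands"
            )


@dataclass
class ConfigTable:
    target: str
    rows: list[ConfigRow] = field(default_factory=list)

    def __post_init__(self):
        names = [r.site_name for r in self.rows]
        if len(set(names)) != len(names):
            raise ValueError(f"config for {self.target!r}: duplicate site names")


def build_config(family: GeneFamily, sites: EnumerationResult, target: str) -> ConfigTable:
    """Assemble the per-target configuration table.

    Row order: the on-target row first, then the retained candidates of each
    sibling amplicon in enumeration sort order.  Site names are
    ``{amplicon}_{label}`` when the site carries a selection label (α, β, ...)
    and ``{amplicon}_{position}{strand-suffix}`` otherwise.
    """
    if target not in family.guides:
        raise KeyError(f"unknown target guide {target!r}")
    guide = family.guides[target]
    own_amp = family.amplicon_of(target)

    rows = [
        ConfigRow(
            site_name=f"{own_amp.name}_on",
            amplicon_name=own_amp.name,
            amplicon_sequence=own_amp.sequence,
            grna=guide.sequence,
            role="on_target",
            source_guide=target,
        )
    ]
    amplicons = family.amplicons
    seen = {rows[0].site_name}
    for (gi, amp_name), candidate_list in sorted(sites.lists.items()):
        if gi != target or amp_name == own_amp.name:
            continue
        for site in candidate_list:
            base = f"{amp_name}_{site.label}" if site.label else f"{amp_name}_{site.position}"
            name = base
            if name in seen:  # two strands can share a window position
                name = f"{base}{'p' if site.strand == '+' else 'm'}"
            seen.add(name)
            rows.append(
                ConfigRow(
                    site_name=name,
                    amplicon_name=amp_name,
                    amplicon_sequence=amplicons[amp_name].sequence,
                    grna=site.protospacer,
                    role="off_target",
                    source_guide=target,
                )
            )
    return ConfigTable(target=target, rows=rows)


def write_config(
    table: ConfigTable,
    path: str | Path,
    dialect: str = "native",
    header_map: dict[str, str] | None = None,
) -> None:
    """Write a config table as CSV.

    ``native`` keeps every field (round-trips through :func:`read_config`);
    ``crispector`` writes only the three columns an external analyzer needs.
    """
    if dialect not in ("native", "crispector"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        if dialect == "native":
            w.writerow(NATIVE_COLUMNS)
            for r in table.rows:
                w.writerow([r.site_name, r.amplicon_name, r.amplicon_sequence,
                            r.grna, r.role, r.source_guide])
        else:
            headers = dict(CRISPECTOR_HEADERS)
            headers.update(header_map or {})
            w.writerow([headers["site_name"], headers["amplicon"], headers["grna"]])
            for r in table.rows:
                w.writerow([r.site_name, r.amplicon_sequence, r.grna])


def read_config(path: str | Path) -> ConfigTable:
    """Read a native-dialect config CSV back into a ConfigTable."""
    rows: list[ConfigRow] = []
    target = ""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(NATIVE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"not a native config file, missing columns {sorted(missing)}")
        for row in reader:
            rows.append(ConfigRow(
                site_name=row["site_name"],
                amplicon_name=row["amplicon_name"],
                amplicon_sequence=row["amplicon_sequence"],
                grna=row["grna"],
                role=row["role"],
                source_guide=row["source_guide"],
            ))
            target = row["source_guide"]
    return ConfigTable(target=target, rows=rows)
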