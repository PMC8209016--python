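"""Study-level report assembly: tables, figures, and a provenance manifest."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from . import __version__

__all__ = ["build_report"]

SECTION_NAMES = ("mri", "nmr", "histology", "echo", "scn")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # Fixed float formatting keeps reruns byte-identical across platforms.
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def build_report(
    out_dir: str | Path,
    sections: dict[str, dict[str, pd.DataFrame]],
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write every section's tables plus a manifest and a Markdown index.

    ``sections`` maps a section name (``mri``, ``nmr``, ``histology``,
    ``echo``, ``scn``) to a dict of table name -> DataFrame.  Sections absent
    from the mapping are flagged as such in the index.  Reruns with identical
    inputs produce byte-identical CSV output.
    """
    if not sections:
        raise ValueError("at least one module output is required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    files: list[str] = []
    for name, tables in sections.items():
        sec_dir = out / name
        sec_dir.mkdir(exist_ok=True)
        for table_name, df in tables.items():
            path = sec_dir / f"{table_name}.csv"
            _write_csv(df, path)
            files.append(str(path.relative_to(out)))

    manifest = {
        "software_version": __version__,
        "seed": seed,
        "config": config or {},
        "files": sorted(files),
        "sections_present": sorted(sections),
        "sections_absent": sorted(set(SECTION_NAMES) - set(sections)),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))

    lines = ["# Study report", ""]
    for name in SECTION_NAMES:
        if name in sections:
            lines.append(f"## {name}")
            for table_name in sections[name]:
                lines.append(f"- [{table_name}]({name}/{table_name}.csv)")
        else:
            lines.append(f"## {name}\n- absent from this run")
        lines.append("")
    (out / "index.md").write_text("\n".join(lines))
    return out
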