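"""Readers and writers: delimited peak lists, MGF spectra, report tables.

Peak lists are comma-delimited UTF-8 text with a mandatory header and at
least an ``mz`` column; ``id``, ``intensity``, ``rt`` and ``adducts``
(``;``-separated hypothesis names) are optional.  Fragment spectra use MGF,
with the TITLE field carrying the observation id so spectra can be joined
to precursor rows.  Writers emit a canonical formatting so that
write(read(x)) round-trips content-identically on simulator output.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import mgf as _mgf

from .annotate import Annotation, FragmentSpectrum, Observation
from .chem import ADDUCT_NAMES

logger = logging.getLogger("depsimatch")


class IOFormatError(ValueError):
    """A file violates the expected dialect."""


class MissingColumnError(IOFormatError):
    """The peak list lacks a required column."""


class MgfFormatError(IOFormatError):
    """An MGF file has unbalanced BEGIN IONS / END IONS blocks."""


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------

def read_peaklist(path: str | Path) -> list[Observation]:
    """Read precursor observations from a delimited peak list.

    Malformed rows (non-numeric or non-positive m/z, unknown adduct names)
    are skipped with a logged warning that carries the file line number.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "mz" not in frame.columns:
        raise MissingColumnError(f"{path}: peak list is missing an 'mz' column")
    observations: list[Observation] = []
    for idx, row in frame.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            mz = float(row["mz"])
            intensity = float(row["intensity"]) if row.get("intensity", "") else 1.0
            rt = float(row["rt"]) if row.get("rt", "") else None
            raw_adducts = row.get("adducts", "")
            adducts = (
                tuple(a.strip() for a in raw_adducts.split(";") if a.strip())
                if raw_adducts
                else ADDUCT_NAMES
            )
            obs = Observation(
                mz=mz,
                intensity=intensity,
                rt=rt,
                adducts=adducts,
                obs_id=str(row.get("id", "")) or f"row{line_no}",
            )
        except (ValueError, KeyError) as exc:
            logger.warning("%s: line %d rejected: %s", path, line_no, exc)
            continue
        observations.append(obs)
    return observations


def write_peaklist(observations: Iterable[Observation], path: str | Path) -> None:
    """Write observations in the canonical peak-list dialect."""
    lines = ["id,mz,intensity,rt,adducts"]
    for obs in observations:
        rt = "" if obs.rt is None else f"{obs.rt:.3f}"
        lines.append(
            f"{obs.obs_id},{obs.mz:.6f},{obs.intensity:.6g},{rt},"
            + ";".join(obs.adducts)
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# MGF fragment spectra
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> dict[str, FragmentSpectrum]:
    """Read fragment spectra keyed by TITLE (observation id).

    Blocks without a TITLE get an auto-generated id; blocks with an empty
    peak list are rejected with a warning.  Unbalanced BEGIN IONS/END IONS
    raises :class:`MgfFormatError`.
    """
    text = Path(path).read_text(encoding="utf-8")
    n_begin = sum(1 for ln in text.splitlines() if ln.strip() == "BEGIN IONS")
    n_end = sum(1 for ln in text.splitlines() if ln.strip() == "END IONS")
    if n_begin != n_end:
        raise MgfFormatError(
            f"{path}: unbalanced BEGIN IONS ({n_begin}) / END IONS ({n_end})"
        )
    spectra: dict[str, FragmentSpectrum] = {}
    with _mgf.MGF(str(path)) as reader:
        for index, block in enumerate(reader, start=1):
            params = block.get("params", {})
            title = str(params.get("title", "")).strip()
            if not title:
                title = f"spectrum_{index:03d}"
                logger.warning("%s: block %d lacks a TITLE; using %r", path, index, title)
            pepmass = params.get("pepmass", (0.0,))
            precursor_mz = float(pepmass[0] if isinstance(pepmass, tuple) else pepmass)
            mz_array = block.get("m/z array")
            intensity_array = block.get("intensity array")
            if mz_array is None or len(mz_array) == 0:
                logger.warning("%s: block %r has no peaks; rejected", path, title)
                continue
            peaks = tuple(
                (float(mz), float(inten))
                for mz, inten in zip(mz_array, intensity_array)
            )
            adduct = str(params.get("adduct", "sodium")).strip() or "sodium"
            spectra[title] = FragmentSpectrum(
                precursor_mz=precursor_mz, peaks=peaks, precursor_adduct=adduct
            )
    return spectra


def write_mgf(spectra: Mapping[str, FragmentSpectrum], path: str | Path) -> None:
    """Write fragment spectra as MGF, one block per observation id."""
    lines: list[str] = []
    for title in spectra:
        spec = spectra[title]
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={title}")
        lines.append(f"PEPMASS={spec.precursor_mz:.6f}")
        lines.append("CHARGE=1+")
        lines.append(f"ADDUCT={spec.precursor_adduct}")
        for mz, inten in spec.peaks:
            lines.append(f"{mz:.6f} {inten:.6g}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# annotation reports
# ---------------------------------------------------------------------------

def annotations_to_frame(annotations: Sequence[Annotation]) -> pd.DataFrame:
    """One row per observation x candidate, ranked, with scores and flags."""
    rows = []
    for ann in annotations:
        base = {
            "obs_id": ann.observation.obs_id,
            "mz": round(ann.observation.mz, 4),
            "rt": ann.observation.rt,
            "status": ann.status,
            "flags": "; ".join(ann.flags),
        }
        if not ann.candidates:
            rows.append({**base, "rank": None})
            continue
        for rank, cand in enumerate(ann.candidates, start=1):
            rows.append(
                {
                    **base,
                    "rank": rank,
                    "composition": cand.composition.key,
                    "formula": str(cand.composition.formula),
                    "adduct": cand.adduct,
                    "theoretical_mz": round(cand.theoretical_mz, 4),
                    "ppm": round(cand.ppm, 2),
                    "coverage": round(cand.coverage, 4),
                    "explained_losses": cand.explained,
                    "names": "/".join(cand.names),
                    "isomer_group": cand.isomer_group,
                    "confidence": cand.confidence,
                }
            )
    return pd.DataFrame(rows)


def write_report(
    annotations: Sequence[Annotation], path: str | Path, fmt: str = "tsv"
) -> None:
    frame = annotations_to_frame(annotations)
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        records = frame.to_dict(orient="records")
        Path(path).write_text(json.dumps(records, indent=1, default=str) + "\n")
    else:
        raise IOFormatError(f"unsupported report format {fmt!r}")


def example_peaklist_path() -> Path:
    """Path of the packaged example peak list (ammoniated analogue ions)."""
    from importlib import resources

    return Path(str(resources.files("depsimatch.data") / "example_peaklist.csv"))
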