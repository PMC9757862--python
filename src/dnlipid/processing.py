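"""Centroided peak lists → filtered, per-mille-normalized lipid matrix.

The processing chain mirrors routine DIMS practice:

1. annotate each theoretical mass-list entry with the nearest observed
   centroid within a 9 ppm window;
2. discard signals with signal/noise ratio < 3 (per-spectrum noise level);
3. discard variables detected in < 50 % of (non-QC) samples;
4. discard variables whose pooled-QC dilution response (0.25x, 0.5x, 1.0x
   plasma) has Pearson correlation <= 0.75 with the dilution factor;
5. divide each sample's retained signals by their total and express per mille
   (each row then sums to 1000);
6. tag diglyceride variables as probable in-source triglyceride fragments
   (values and names untouched — DG species stay reported as DG).

Positive- and negative-mode peak lists are processed against their own mass
lists; a subject's variables from both modes are concatenated into one row
and normalized over the concatenated row, matching a single per-individual
total lipid signal.
"""

from __future__ import annotations

import base64
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.sax.saxutils import escape, quoteattr

import numpy as np
import pandas as pd

from .masslist import AdductIon, LipidSpecies, MassList

logger = logging.getLogger(__name__)

DEFAULT_TOL_PPM = 9.0
DEFAULT_MIN_SNR = 3.0
DEFAULT_MIN_PRESENCE = 0.5
DEFAULT_QC_R = 0.75


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------


@dataclass
class PeakList:
    """One sample's centroided spectrum in one polarity."""

    sample_id: str
    polarity: str
    mz: np.ndarray
    intensity: np.ndarray
    noise_level: float | None = None
    is_qc: bool = False
    qc_dilution: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity lengths differ")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        if self.noise_level is not None and not (self.noise_level > 0):
            raise ValueError("noise_level must be positive")
        if self.is_qc != (self.qc_dilution is not None):
            raise ValueError("qc_dilution must be present iff is_qc")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            raise ValueError("peaks must be sorted by m/z")

    def __len__(self) -> int:
        return int(self.mz.size)


def read_peaklist_csv(
    path: str | Path,
    sample_id: str | None = None,
    polarity: str | None = None,
    is_qc: bool = False,
    qc_dilution: float | None = None,
) -> PeakList:
    """Read a ``mz,intensity[,noise]`` CSV into a PeakList.

    Sample id and polarity default to parsing the file stem as
    ``<sample>_<pos|neg>``. An empty file yields an empty PeakList with a
    warning; unsorted rows are sorted with a warning.
    """
    path = Path(path)
    stem = path.stem
    if sample_id is None or polarity is None:
        parts = stem.rsplit("_", 1)
        tok = parts[-1].lower() if len(parts) == 2 else ""
        pol_map = {"pos": "positive", "neg": "negative",
                   "positive": "positive", "negative": "negative"}
        if polarity is None:
            if tok not in pol_map:
                raise ValueError(
                    f"cannot infer polarity from filename {path.name!r}; "
                    "use <sample>_<pos|neg>.csv or pass polarity="
                )
            polarity = pol_map[tok]
        if sample_id is None:
            sample_id = parts[0] if tok in pol_map else stem
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        warnings.warn(f"empty peak list file {path.name}", stacklevel=2)
        return PeakList(sample_id, polarity, np.array([]), np.array([]),
                        noise_level=None if not is_qc else 1.0,
                        is_qc=is_qc, qc_dilution=qc_dilution)
    # tolerate a header row
    if not np.issubdtype(np.asarray(df.iloc[0, 0]).dtype, np.number):
        try:
            float(df.iloc[0, 0])
        except (TypeError, ValueError):
            df = df.iloc[1:].reset_index(drop=True)
    df = df.apply(pd.to_numeric)
    mz = df.iloc[:, 0].to_numpy(float)
    inten = df.iloc[:, 1].to_numpy(float)
    noise = float(np.median(df.iloc[:, 2])) if df.shape[1] > 2 else None
    if mz.size and np.any(np.diff(mz) < 0):
        warnings.warn(f"unsorted peak list {path.name}; sorting", stacklevel=2)
        order = np.argsort(mz)
        mz, inten = mz[order], inten[order]
    return PeakList(sample_id, polarity, mz, inten, noise_level=noise,
                    is_qc=is_qc, qc_dilution=qc_dilution)


def write_peaklist_csv(pl: PeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m, i in zip(pl.mz, pl.intensity):
            if pl.noise_level is not None:
                fh.write(f"{m:.6f},{i:.4f},{pl.noise_level:.4f}\n")
            else:
                fh.write(f"{m:.6f},{i:.4f}\n")


def read_qc_manifest(path: str | Path) -> dict[str, float]:
    """QC manifest CSV (``sample_id,dilution``) → {sample_id: dilution}."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "dilution" not in cols:
        raise ValueError("QC manifest must have columns sample_id,dilution")
    return dict(zip(df[cols["sample_id"]].astype(str),
                    df[cols["dilution"]].astype(float)))


# ---------------------------------------------------------------------------
# Minimal centroided mzML I/O (read via pyteomics; writer produces the small
# subset of mzML the reader needs: centroided spectra with polarity, binary
# little-endian float64 m/z and intensity arrays, and a noise-level userParam).
# ---------------------------------------------------------------------------


def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode()


def write_mzml(peaklists: Sequence[PeakList], path: str | Path) -> None:
    """Write centroided peak lists as a minimal mzML file."""
    pol_cv = {
        "positive": ("MS:1000130", "positive scan"),
        "negative": ("MS:1000129", "negative scan"),
    }
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        "<run id=\"run1\">",
        f'<spectrumList count="{len(peaklists)}">',
    ]
    for i, pl in enumerate(peaklists):
        mz_b64 = _encode_array(pl.mz)
        in_b64 = _encode_array(pl.intensity)
        acc, pname = pol_cv[pl.polarity]
        spec_id = f"sample={pl.sample_id}"
        lines.append(
            f'<spectrum index="{i}" id={quoteattr(spec_id)} '
            f'defaultArrayLength="{len(pl)}">'
        )
        lines.append(
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>'
        )
        lines.append(
            f'<cvParam cvRef="MS" accession="{acc}" name="{pname}"/>'
        )
        if pl.noise_level is not None:
            lines.append(
                f'<userParam name="noise_level" value="{pl.noise_level!r}" '
                'type="xsd:double"/>'
            )
        if pl.is_qc:
            lines.append(
                f'<userParam name="qc_dilution" value="{pl.qc_dilution!r}" '
                'type="xsd:double"/>'
            )
        lines.append('<binaryDataArrayList count="2">')
        for name_acc, name, b64 in (
            ("MS:1000514", "m/z array", mz_b64),
            ("MS:1000515", "intensity array", in_b64),
        ):
            lines.append(f'<binaryDataArray encodedLength="{len(b64)}">')
            lines.append(
                '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
            )
            lines.append(
                '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
            )
            lines.append(
                f'<cvParam cvRef="MS" accession="{name_acc}" name="{name}"/>'
            )
            lines.append(f"<binary>{b64}</binary>")
            lines.append("</binaryDataArray>")
        lines.append("</binaryDataArrayList>")
        lines.append("</spectrum>")
    lines += ["</spectrumList>", "</run>", "</mzML>"]
    Path(path).write_text("\n".join(lines))


def _decode_binary(elem, ns: str) -> np.ndarray:
    names = {c.get("name") for c in elem.findall(f"{ns}cvParam")}
    b64 = elem.findtext(f"{ns}binary") or ""
    raw = base64.b64decode(b64)
    if "zlib compression" in names:
        import zlib

        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in names else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> list[PeakList]:
    """Read centroided spectra from mzML (profile-mode spectra are rejected).

    A deliberately small reader for the subset of mzML this pipeline consumes:
    centroided full-scan spectra with declared polarity and uncompressed or
    zlib-compressed float32/float64 m/z and intensity arrays. Optional
    ``noise_level`` and ``qc_dilution`` userParams are honored.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(str(path)).getroot()
    ns = root.tag[: root.tag.index("}") + 1] if root.tag.startswith("{") else ""
    out = []
    for spec in root.iter(f"{ns}spectrum"):
        cv_names = {c.get("name") for c in spec.findall(f"{ns}cvParam")}
        user = {
            u.get("name"): u.get("value") for u in spec.findall(f"{ns}userParam")
        }
        if "profile spectrum" in cv_names:
            raise ValueError(
                f"{path}: profile-mode spectra are unsupported; centroid the "
                "data upstream (e.g. with the instrument software or XCMS) "
                "before import"
            )
        if "centroid spectrum" not in cv_names:
            raise ValueError(f"{path}: spectrum mode not declared as centroid")
        if "positive scan" in cv_names:
            polarity = "positive"
        elif "negative scan" in cv_names:
            polarity = "negative"
        else:
            raise ValueError(f"{path}: spectrum polarity not declared")
        sid = spec.get("id", "")
        sample_id = sid.split("sample=", 1)[1] if "sample=" in sid else sid
        mz = inten = None
        for arr in spec.iter(f"{ns}binaryDataArray"):
            arr_names = {c.get("name") for c in arr.findall(f"{ns}cvParam")}
            data = _decode_binary(arr, ns)
            if "m/z array" in arr_names:
                mz = data
            elif "intensity array" in arr_names:
                inten = data
        if mz is None or inten is None:
            raise ValueError(f"{path}: spectrum {sid!r} lacks m/z or intensity array")
        noise = user.get("noise_level")
        qc_dilution = user.get("qc_dilution")
        out.append(
            PeakList(
                sample_id,
                polarity,
                mz,
                inten,
                noise_level=float(noise) if noise is not None else None,
                is_qc=qc_dilution is not None,
                qc_dilution=float(qc_dilution) if qc_dilution is not None else None,
            )
        )
    return out


def read_peaklists(
    paths: Iterable[str | Path],
    format: str | None = None,
    qc_manifest: Mapping[str, float] | None = None,
) -> list[PeakList]:
    """Read peak lists from CSV or mzML files; one PeakList per sample/polarity.

    QC membership and dilution factors are assigned from ``qc_manifest``
    (sample_id → dilution) where the file itself does not carry them.
    """
    out: list[PeakList] = []
    for p in paths:
        p = Path(p)
        fmt = format or ("mzml" if p.suffix.lower() == ".mzml" else "csv")
        if fmt == "mzml":
            out.extend(read_mzml(p))
        elif fmt == "csv":
            out.append(read_peaklist_csv(p))
        else:
            raise ValueError(f"unknown peak-list format {fmt!r}")
    if qc_manifest:
        out = [
            replace(pl, is_qc=True, qc_dilution=float(qc_manifest[pl.sample_id]))
            if (not pl.is_qc and pl.sample_id in qc_manifest)
            else pl
            for pl in out
        ]
    return out


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotatedSignal:
    """A mass-list entry matched to an observed centroid."""

    species: LipidSpecies
    adduct: AdductIon
    observed_mz: float
    ppm_deviation: float
    intensity: float
    snr: float

    @property
    def variable_id(self) -> str:
        return f"{self.species.name}|{self.adduct.label}|{self.adduct.polarity}"


def annotate_peaks(
    pl: PeakList, ml: MassList, tol_ppm: float = DEFAULT_TOL_PPM
) -> list[AnnotatedSignal]:
    """Assign each mass-list entry its nearest peak within ``tol_ppm``.

    ppm deviation is (observed − theoretical)/theoretical × 1e6; entries with
    no peak inside the window yield no signal. When two peaks are exactly
    equidistant in |ppm| the more intense wins. If the peak list carries no
    noise level, it is estimated as the median intensity of unannotated peaks
    (falling back to the overall median); snr = intensity / noise_level.
    """
    if pl.polarity != ml.polarity:
        raise ValueError(
            f"peak list polarity {pl.polarity} does not match mass list {ml.polarity}"
        )
    if len(pl) == 0 or len(ml) == 0:
        return []
    theo = ml.mzs()
    idx = np.searchsorted(pl.mz, theo)
    left = np.clip(idx - 1, 0, len(pl) - 1)
    right = np.clip(idx, 0, len(pl) - 1)
    ppm_left = (pl.mz[left] - theo) / theo * 1e6
    ppm_right = (pl.mz[right] - theo) / theo * 1e6
    pick_left = np.abs(ppm_left) < np.abs(ppm_right)
    ties = np.abs(ppm_left) == np.abs(ppm_right)
    # exact |ppm| tie between two distinct peaks: higher intensity wins
    pick_left |= ties & (pl.intensity[left] > pl.intensity[right])
    chosen = np.where(pick_left, left, right)
    ppm = np.where(pick_left, ppm_left, ppm_right)
    within = np.abs(ppm) <= tol_ppm

    matched_peaks = set(chosen[within].tolist())
    if pl.noise_level is not None:
        noise = pl.noise_level
    else:
        unmatched = np.array(
            [i for i in range(len(pl)) if i not in matched_peaks], dtype=int
        )
        pool = pl.intensity[unmatched] if unmatched.size else pl.intensity
        noise = float(np.median(pool)) if pool.size else 1.0
        if not noise > 0:
            noise = 1.0
    out = []
    for k in np.nonzero(within)[0]:
        entry = ml.entries[int(k)]
        inten = float(pl.intensity[chosen[k]])
        out.append(
            AnnotatedSignal(
                species=entry.species,
                adduct=entry.adduct,
                observed_mz=float(pl.mz[chosen[k]]),
                ppm_deviation=float(ppm[k]),
                intensity=inten,
                snr=inten / noise,
            )
        )
    return out


def filter_snr(
    signals: Sequence[AnnotatedSignal], min_snr: float = DEFAULT_MIN_SNR
) -> list[AnnotatedSignal]:
    """Retain signals with signal/noise ratio >= ``min_snr`` (boundary kept)."""
    return [s for s in signals if s.snr >= min_snr]


# ---------------------------------------------------------------------------
# Lipid matrix and matrix-level filters
# ---------------------------------------------------------------------------


@dataclass
class LipidMatrix:
    """Samples × lipid-variables signal table with filter provenance.

    ``values`` rows are samples, columns are ``species|adduct|polarity``
    variable ids. ``filter_log`` records one row per filter decision
    (variable, filter, statistic, threshold, decision). ``var_tags`` carries
    interpretation tags such as the TG-fragment annotation on DG variables.
    """

    values: pd.DataFrame
    normalized: bool = False
    filter_log: list[dict] = field(default_factory=list)
    var_tags: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variable_ids(self) -> list[str]:
        return list(self.values.columns)

    def filter_log_frame(self) -> pd.DataFrame:
        cols = ["variable", "filter", "statistic", "threshold", "decision"]
        return pd.DataFrame(self.filter_log, columns=cols)

    def subset_variables(self, variables: Sequence[str]) -> "LipidMatrix":
        """Column subset; warns if rows were already normalized (their
        per-mille sums no longer hold and need re-normalization)."""
        if self.normalized and set(variables) != set(self.values.columns):
            warnings.warn(
                "subsetting a per-mille-normalized matrix: row sums no longer "
                "equal 1000; re-run normalize_per_mille",
                stacklevel=2,
            )
        return LipidMatrix(
            self.values[list(variables)].copy(),
            normalized=self.normalized,
            filter_log=list(self.filter_log),
            var_tags={v: t for v, t in self.var_tags.items() if v in set(variables)},
        )


def matrix_from_annotations(
    signals_by_sample: Mapping[str, Sequence[AnnotatedSignal]]
) -> LipidMatrix:
    """Raw matrix from per-sample annotated signals; absent signals are 0."""
    records = {
        sid: {s.variable_id: s.intensity for s in signals}
        for sid, signals in signals_by_sample.items()
    }
    df = pd.DataFrame.from_dict(records, orient="index").fillna(0.0)
    df = df.reindex(sorted(df.columns), axis=1)
    df.index.name = "sample_id"
    return LipidMatrix(df)


def filter_presence(
    matrix: LipidMatrix, min_fraction: float = DEFAULT_MIN_PRESENCE
) -> LipidMatrix:
    """Retain variables detected (> 0) in at least ``min_fraction`` of samples.

    The boundary is inclusive (a variable in exactly 50 % of samples stays).
    QC samples must already be excluded from ``matrix``.
    """
    if matrix.normalized:
        raise ValueError("presence filter must run on the raw matrix")
    frac = (matrix.values > 0).mean(axis=0)
    keep = frac >= min_fraction
    log = list(matrix.filter_log)
    for var in matrix.values.columns:
        log.append(
            {
                "variable": var,
                "filter": "presence",
                "statistic": float(frac[var]),
                "threshold": min_fraction,
                "decision": "retained" if keep[var] else "removed",
            }
        )
    return LipidMatrix(
        matrix.values.loc[:, keep].copy(),
        normalized=False,
        filter_log=log,
        var_tags=dict(matrix.var_tags),
    )


def qc_linearity_filter(
    matrix: LipidMatrix,
    qc_matrix: pd.DataFrame,
    qc_dilutions: Mapping[str, float],
    r_min: float = DEFAULT_QC_R,
) -> LipidMatrix:
    """Retain variables whose QC signal correlates with dilution (r > r_min).

    ``qc_matrix`` holds QC samples × variables; ``qc_dilutions`` maps each QC
    sample id to its dilution factor. Pearson correlation is computed on raw
    intensities against the dilution factor; variables with zero variance
    across QCs have undefined r and are removed. Requires at least two
    distinct dilution levels.
    """
    if not qc_dilutions:
        raise ValueError("QC manifest is missing: the linearity filter cannot run")
    qc_ids = [s for s in qc_matrix.index if s in qc_dilutions]
    if not qc_ids:
        raise ValueError("no QC samples with known dilutions")
    dil = np.array([qc_dilutions[s] for s in qc_ids])
    if len(np.unique(dil)) < 2:
        raise ValueError("QC linearity filter needs >= 2 distinct dilution levels")
    sub = qc_matrix.loc[qc_ids]
    log = list(matrix.filter_log)
    keep = []
    dil_c = dil - dil.mean()
    for var in matrix.values.columns:
        y = sub[var].to_numpy(float) if var in sub.columns else np.zeros(len(qc_ids))
        y_c = y - y.mean()
        denom = math.sqrt(float((y_c**2).sum()) * float((dil_c**2).sum()))
        if denom == 0.0:
            r = float("nan")
            retained = False
        else:
            r = float((y_c * dil_c).sum() / denom)
            retained = r > r_min
        keep.append(retained)
        log.append(
            {
                "variable": var,
                "filter": "qc_linearity",
                "statistic": r,
                "threshold": r_min,
                "decision": "retained" if retained else "removed",
            }
        )
    keep_arr = np.array(keep, dtype=bool)
    return LipidMatrix(
        matrix.values.loc[:, keep_arr].copy(),
        normalized=matrix.normalized,
        filter_log=log,
        var_tags=dict(matrix.var_tags),
    )


def normalize_per_mille(matrix: LipidMatrix) -> LipidMatrix:
    """Divide each row by its total signal and express per mille (sums to 1000)."""
    totals = matrix.values.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"cannot normalize all-zero sample row(s): {', '.join(map(str, zero.index))}"
        )
    values = matrix.values.div(totals, axis=0) * 1000.0
    return LipidMatrix(
        values,
        normalized=True,
        filter_log=list(matrix.filter_log),
        var_tags=dict(matrix.var_tags),
    )


TG_FRAGMENT_TAG = "TG-fragment"


def reclassify_dg(matrix: LipidMatrix) -> LipidMatrix:
    """Tag DG variables as probable in-source TG fragments.

    Triglycerides fragment during DIMS analysis and appear as diglycerides, so
    DG signals most likely represent TG in vivo; they keep their DG names and
    values and only carry the interpretation tag.
    """
    tags = dict(matrix.var_tags)
    for var in matrix.values.columns:
        if var.startswith("DG("):
            tags[var] = TG_FRAGMENT_TAG
    return LipidMatrix(
        matrix.values.copy(),
        normalized=matrix.normalized,
        filter_log=list(matrix.filter_log),
        var_tags=tags,
    )


# ---------------------------------------------------------------------------
# High-level chain
# ---------------------------------------------------------------------------


def process_peaklists(
    peaklists: Sequence[PeakList],
    masslists: Mapping[str, MassList] | MassList,
    tol_ppm: float = DEFAULT_TOL_PPM,
    min_snr: float = DEFAULT_MIN_SNR,
    min_presence: float = DEFAULT_MIN_PRESENCE,
    qc_r: float = DEFAULT_QC_R,
    require_qc: bool = True,
) -> LipidMatrix:
    """Full chain: annotate → S/N → presence → QC linearity → per-mille → tags.

    Sample peak lists from both polarities are annotated against their own
    mass list and concatenated per subject before normalization; QC peak lists
    drive the linearity filter and are excluded from the output matrix and
    from the presence denominator.
    """
    if isinstance(masslists, MassList):
        masslists = {masslists.polarity: masslists}
    sample_signals: dict[str, list[AnnotatedSignal]] = {}
    qc_signals: dict[str, list[AnnotatedSignal]] = {}
    qc_dilutions: dict[str, float] = {}
    order_ids: list[str] = []
    for pl in peaklists:
        ml = masslists.get(pl.polarity)
        if ml is None:
            raise ValueError(f"no mass list for polarity {pl.polarity!r}")
        signals = filter_snr(annotate_peaks(pl, ml, tol_ppm), min_snr)
        if pl.is_qc:
            qc_signals.setdefault(pl.sample_id, []).extend(signals)
            qc_dilutions[pl.sample_id] = float(pl.qc_dilution)
        else:
            if pl.sample_id not in sample_signals:
                order_ids.append(pl.sample_id)
            sample_signals.setdefault(pl.sample_id, []).extend(signals)
    logger.info(
        "annotated %d samples and %d QCs", len(sample_signals), len(qc_signals)
    )
    matrix = matrix_from_annotations(sample_signals)
    # deterministic sample order regardless of input file order
    matrix.values = matrix.values.reindex(sorted(order_ids))
    matrix = filter_presence(matrix, min_presence)
    if qc_signals:
        qc_matrix = matrix_from_annotations(qc_signals).values
        qc_matrix = qc_matrix.reindex(columns=matrix.values.columns, fill_value=0.0)
        matrix = qc_linearity_filter(matrix, qc_matrix, qc_dilutions, qc_r)
    elif require_qc:
        raise ValueError("QC peak lists are missing: the linearity filter cannot run")
    matrix = normalize_per_mille(matrix)
    matrix = reclassify_dg(matrix)
    n_removed = sum(1 for e in matrix.filter_log if e["decision"] == "removed")
    logger.info(
        "matrix: %d samples x %d variables (%d filter removals)",
        matrix.values.shape[0], matrix.values.shape[1], n_removed,
    )
    return matrix
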