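"""Maximum-likelihood index demultiplexing.

Each read's observed index is scored against every candidate barcode with a
per-position model: a matched base is correct with probability ``1 - e_i``
(``e_i = 10**(-Q_i/10)`` from the Phred score), a mismatched base arises by
substitution with probability ``e_i / 3``, and an ``N`` in either sequence
contributes a flat 1/4 and is excluded from the summary statistic. The read is
routed to the candidate with maximal log-likelihood and accepted or rejected
on a decibel-scale statistic built from the geometric means of the matched and
mismatched position probabilities:

    Z = -10*log10(unmatched_gm) + 10*log10(matched_gm)

Low-quality mismatch evidence (large ``e_i``) drives Z down toward and below
the acceptance threshold; perfect matches bypass the threshold entirely, and
ties between the top two candidates are never broken arbitrarily - the read is
left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BarcodeError, TableParseError
from .simulate import _validate_barcodes

_CODE = {c: i for i, c in enumerate("ACGTN")}
_N = 4
_TIE_TOL = 1e-9

DEFAULT_THRESHOLD = 6.0


@dataclass
class DemuxAssignment:
    read_id: str
    assigned_sample: str | None
    z_score: float
    n_mismatch: int
    matched_gm: float
    unmatched_gm: float
    reason: str  # assigned | perfect | tie | low_z


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise TableParseError(f"invalid base {exc} in sequence {seq!r}") from exc


def _phred_errors(qualities) -> np.ndarray:
    """Per-base error probabilities from a Phred+33 string or integer array."""
    if isinstance(qualities, str):
        q = np.array([ord(c) - 33 for c in qualities], dtype=float)
        if np.any(q < 0) or np.any(q > 60):
            raise TableParseError(f"invalid Phred character in {qualities!r}")
    else:
        q = np.asarray(qualities, dtype=float)
        if np.any(q < 0):
            raise TableParseError("negative Phred score")
    return 10.0 ** (-q / 10.0)


def barcode_likelihood(observed_index: str, qualities, candidate_barcode: str):
    """Matched/unmatched geometric means and log-likelihood for one candidate.

    Returns ``(matched_gm, unmatched_gm, log_likelihood)``. A geometric mean
    over an empty position set is 1 by convention.
    """
    obs = _encode(observed_index)
    bc = _encode(candidate_barcode)
    e = _phred_errors(qualities)
    if not (obs.size == bc.size == e.size):
        raise TableParseError(
            f"length mismatch: index {obs.size}, qualities {e.size}, barcode {bc.size}"
        )
    nmask = (obs == _N) | (bc == _N)
    match = (obs == bc) & ~nmask
    mismatch = (obs != bc) & ~nmask
    ll = nmask.sum() * np.log(0.25)
    ll += np.log1p(-e[match]).sum() + np.log(e[mismatch] / 3.0).sum()
    matched_gm = float(np.exp(np.log1p(-e[match]).mean())) if match.any() else 1.0
    unmatched_gm = float(np.exp(np.log(e[mismatch] / 3.0).mean())) if mismatch.any() else 1.0
    return matched_gm, unmatched_gm, float(ll)


def z_statistic(matched_gm: float, unmatched_gm: float) -> float:
    """Decibel-scale acceptance statistic from the two geometric means."""
    if not (0.0 < matched_gm <= 1.0) or not (0.0 < unmatched_gm <= 1.0):
        raise ValueError("geometric means must lie in (0, 1]")
    return float(-10.0 * np.log10(unmatched_gm) + 10.0 * np.log10(matched_gm))


def assign_read(
    observed_index: str,
    qualities,
    barcode_set: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    read_id: str = "read",
) -> DemuxAssignment:
    """Assign one read to the maximum-likelihood barcode, or leave unassigned.

    ``barcode_set`` is a table with columns ``sample_id, index1`` (dual-index
    sets concatenate ``index1+index2`` upstream). Perfect matches (0 mismatches
    and no N) are always assigned; top-two log-likelihood ties and Z <=
    ``threshold`` are left unassigned.
    """
    if barcode_set is None or len(barcode_set) == 0:
        raise BarcodeError("empty barcode set")
    stats = [
        barcode_likelihood(observed_index, qualities, bc)
        for bc in barcode_set["index1"]
    ]
    ll = np.array([s[2] for s in stats])
    order = np.argsort(ll)[::-1]
    best = order[0]
    m_gm, u_gm, _ = stats[best]
    obs = _encode(observed_index)
    bc = _encode(barcode_set["index1"].iloc[best])
    nmask = (obs == _N) | (bc == _N)
    nmm = int(((obs != bc) & ~nmask).sum())
    z = z_statistic(m_gm, u_gm)
    sample = str(barcode_set["sample_id"].iloc[best])

    if nmm == 0 and not nmask.any():
        return DemuxAssignment(read_id, sample, z, 0, m_gm, u_gm, "perfect")
    if len(ll) > 1 and ll[order[0]] - ll[order[1]] <= _TIE_TOL:
        return DemuxAssignment(read_id, None, z, nmm, m_gm, u_gm, "tie")
    if z <= threshold:
        return DemuxAssignment(read_id, None, z, nmm, m_gm, u_gm, "low_z")
    return DemuxAssignment(read_id, sample, z, nmm, m_gm, u_gm, "assigned")


# ---------------------------------------------------------------------------
# vectorized batch engine
# ---------------------------------------------------------------------------

def _pool_indices(reads: pd.DataFrame, barcode_set: pd.DataFrame):
    """Concatenate dual indices (pooled position sets, summed log-likelihoods)."""
    dual = "index2" in reads.columns and "index2" in barcode_set.columns
    if dual:
        seqs = reads["index1"].str.cat(reads["index2"])
        quals = reads["qual1"].str.cat(reads["qual2"])
        bcs = barcode_set["index1"].str.cat(barcode_set["index2"])
    else:
        seqs, quals, bcs = reads["index1"], reads["qual1"], barcode_set["index1"]
    return seqs.to_numpy(), quals.to_numpy(), bcs.to_numpy()


def assign_reads(
    reads: pd.DataFrame,
    barcode_set: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    chunk: int = 2048,
) -> pd.DataFrame:
    """Vectorized demultiplexing of a read table.

    ``reads`` needs columns ``read_id, index1, qual1`` (plus ``index2, qual2``
    for dual-index runs). Returns one row per read with the assignment, Z
    statistic, mismatch count and both geometric means; unassigned reads carry
    an empty ``assigned_sample`` and the rejection reason.
    """
    if barcode_set is None or len(barcode_set) == 0:
        raise BarcodeError("empty barcode set")
    _validate_barcodes(barcode_set)
    seqs, quals, bcs = _pool_indices(reads, barcode_set)
    L = len(bcs[0])
    B = np.vstack([_encode(b) for b in bcs])  # (n_bc, L)
    samples = barcode_set["sample_id"].to_numpy()

    out = []
    for lo in range(0, len(seqs), chunk):
        sl = slice(lo, min(lo + chunk, len(seqs)))
        R = np.vstack([_encode(s) for s in seqs[sl]])  # (n, L)
        E = np.vstack([_phred_errors(q) for q in quals[sl]])  # (n, L)
        if R.shape[1] != L:
            raise TableParseError("read index length differs from barcode length")

        nmask = (R[:, None, :] == _N) | (B[None, :, :] == _N)  # (n, b, L)
        match = (R[:, None, :] == B[None, :, :]) & ~nmask
        mism = ~match & ~nmask
        log_match = np.log1p(-E)[:, None, :]
        log_mism = np.log(E / 3.0)[:, None, :]
        ll = (
            np.where(match, log_match, 0.0).sum(axis=2)
            + np.where(mism, log_mism, 0.0).sum(axis=2)
            + nmask.sum(axis=2) * np.log(0.25)
        )  # (n, b)

        part = np.argpartition(ll, -2, axis=1)[:, -2:] if ll.shape[1] > 1 else None
        best = np.argmax(ll, axis=1)
        if part is not None:
            top2 = np.sort(np.take_along_axis(ll, part, axis=1), axis=1)
            tie = (top2[:, 1] - top2[:, 0]) <= _TIE_TOL
        else:
            tie = np.zeros(len(best), dtype=bool)

        rows = np.arange(len(best))
        bmatch = match[rows, best]  # (n, L)
        bmism = mism[rows, best]
        bn = nmask[rows, best]
        n_match = bmatch.sum(axis=1)
        n_mism = bmism.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            m_gm = np.where(
                n_match > 0,
                np.exp(np.where(bmatch, np.log1p(-E), 0.0).sum(axis=1) / np.maximum(n_match, 1)),
                1.0,
            )
            u_gm = np.where(
                n_mism > 0,
                np.exp(np.where(bmism, np.log(E / 3.0), 0.0).sum(axis=1) / np.maximum(n_mism, 1)),
                1.0,
            )
        z = -10.0 * np.log10(u_gm) + 10.0 * np.log10(m_gm)

        perfect = (n_mism == 0) & (~bn.any(axis=1))
        assigned = perfect | ((~tie) & (z > threshold))
        reason = np.where(
            perfect, "perfect", np.where(tie, "tie", np.where(z > threshold, "assigned", "low_z"))
        )
        out.append(
            pd.DataFrame(
                {
                    "read_id": np.asarray(reads["read_id"])[sl],
                    "assigned_sample": np.where(assigned, samples[best], ""),
                    "z_score": z,
                    "n_mismatch": n_mism.astype(int),
                    "matched_gm": m_gm,
                    "unmatched_gm": u_gm,
                    "reason": reason,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def calibrate_threshold(control_z, target_exclusion: float = 1.0) -> int:
    """Smallest integer t excluding at least ``target_exclusion`` of controls.

    ``control_z`` are Z scores of reads known to be spurious (e.g. simulated
    2-3-mismatch, high-error controls); a read is excluded when Z <= t.
    """
    from .errors import CalibrationError

    if hasattr(control_z, "columns"):
        control_z = control_z["z_score"]
    z = np.asarray(control_z, dtype=float)
    if z.size == 0:
        raise CalibrationError("no control assignments supplied")
    if not 0.0 < target_exclusion <= 1.0:
        raise CalibrationError("target_exclusion must lie in (0, 1]")
    for t in range(int(np.floor(z.min())), int(np.ceil(z.max())) + 1):
        if (z <= t).mean() >= target_exclusion:
            return t
    return int(np.ceil(z.max()))
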