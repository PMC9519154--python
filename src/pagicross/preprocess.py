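"""Count filtering, TPM normalisation and lncRNA differential expression.

The DE test is a documented stand-in for a negative-binomial Wald test:
median-of-ratios size factors, log2(count/size_factor + 1) normalisation, and
a Welch two-sample t-test, with significance at p < 0.05 and |log2FC| > 0.5.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, DataError

logger = logging.getLogger(__name__)


def cpm_filter(m: CountMatrix, threshold: float = 1.0,
               frac: float = 0.5) -> CountMatrix:
    """Drop genes below ``threshold`` CPM in at least ``frac`` of samples.

    A gene is removed when the fraction of samples with CPM below the
    threshold is >= ``frac`` ("at least 50%" removes at exactly one half),
    and retained otherwise. CPM_gs = count_gs / (library_size_s / 1e6).
    """
    if m.counts.shape[1] == 0:
        raise DataError("count matrix has no samples")
    libsize = m.counts.sum(axis=0).to_numpy(dtype=float)
    if (libsize <= 0).any():
        raise DataError("library sizes must be positive")
    cpm = m.counts.to_numpy(dtype=float) / (libsize / 1e6)
    below = (cpm < threshold).mean(axis=1)
    keep = below < frac
    if not keep.any():
        raise DataError("CPM filter removed every gene")
    return CountMatrix(m.counts.loc[keep], m.pheno.copy())


def tpm_normalize(m: CountMatrix, lengths: pd.Series,
                  log_transform: bool = True) -> pd.DataFrame:
    """Length- then library-normalise to TPM; optionally log2(TPM+1).

    Each sample's TPM column sums to 1e6 before the log transform.
    """
    missing = [g for g in m.counts.index if g not in lengths.index]
    if missing:
        raise DataError(f"genes without length annotation: {missing[:10]}"
                        + ("..." if len(missing) > 10 else ""))
    lens = lengths.loc[m.counts.index].to_numpy(dtype=float)
    if (lens <= 0).any():
        raise DataError("gene lengths must be positive")
    rate = m.counts.to_numpy(dtype=float) / lens[:, None]
    denom = rate.sum(axis=0)
    zero = np.where(denom == 0)[0]
    if zero.size:
        bad = [m.sample_ids[i] for i in zero]
        raise DataError(f"all-zero samples (zero rate sum): {bad}")
    tpm = 1e6 * rate / denom
    if log_transform:
        tpm = np.log2(tpm + 1.0)
    return pd.DataFrame(tpm, index=m.counts.index, columns=m.counts.columns)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference: per-gene geometric mean
    over genes with all-positive counts)."""
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise DataError("no gene with all-positive counts; cannot compute "
                        "size factors")
    ref = np.exp(np.log(x[allpos]).mean(axis=1))
    ratios = x[allpos] / ref[:, None]
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def de_lncrna(m: CountMatrix, p_cut: float = 0.05,
              lfc_cut: float = 0.5) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group differential expression on size-factor-normalised counts.

    Returns a per-gene table (log2FC = case minus control on the
    log2(count/sf + 1) scale, Welch-t p-value, significance flag) and the
    size factors used.
    """
    groups = m.pheno["group"]
    case = m.counts.columns[(groups == "AD").to_numpy()]
    ctrl = m.counts.columns[(groups == "control").to_numpy()]
    if len(case) < 2 or len(ctrl) < 2:
        raise DataError("each group needs at least 2 samples for DE testing")
    if "batch" in m.pheno.columns and m.pheno["batch"].nunique() > 1:
        logger.warning("multiple batch labels present; DE test does not "
                       "adjust for batch")
    sf = size_factors(m.counts)
    y = np.log2(m.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    ydf = pd.DataFrame(y, index=m.counts.index, columns=m.counts.columns)
    ya = ydf[case].to_numpy()
    yb = ydf[ctrl].to_numpy()
    lfc = ya.mean(axis=1) - yb.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(ya, yb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    out = pd.DataFrame(
        {
            "log2FC": lfc,
            "p_value": p,
            "significant": (p < p_cut) & (np.abs(lfc) > lfc_cut),
        },
        index=m.counts.index,
    )
    out.index.name = "gene"
    return out, sf
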