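"""Per-ASV host-specificity statistics.

Two complementary measures:

* **Pielou-evenness SES** — how evenly an ASV's occurrences spread over the
  order-level host taxa of one class.  The observed evenness J is compared to
  a permutation null that redraws, for each ASV, the same number of occupied
  samples uniformly (without replacement) from the class's samples, so uneven
  sampling across orders is controlled for.  SES = (J_obs - mean(J_null)) /
  sd(J_null); strongly negative SES means the ASV is far more host-restricted
  than sampling imbalance alone would produce.

* **Log risk ratio (LRR)** — ln of the ratio of an ASV's prevalence in one
  host class (mammals, by default) to its prevalence in another (birds).
  Class-exclusive ASVs get the cap value +/-cap; a per-sample mean LRR then
  summarizes how class-specific each sample's community is.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from phylosym._seeding import substream
from phylosym.containers import FeatureTable, SampleMetadata

__all__ = [
    "taxon_incidence",
    "pielou_evenness",
    "evenness_ses",
    "log_risk_ratio",
    "sample_mean_lrr",
]


def taxon_incidence(
    table: FeatureTable,
    metadata: SampleMetadata,
    class_name: str,
    level: str = "host_order",
) -> pd.DataFrame:
    """Per-ASV incidence vector across the class's taxa at ``level``.

    Returns an (ASV x taxon) integer frame: the number of the class's samples
    from each taxon in which the ASV is present.  Taxa with no occurrences of
    a given ASV contribute zero entries (all taxa of the class present in the
    data set are columns).
    """
    samples = [s for s in table.sample_ids if s in set(metadata.samples_of_class(class_name))]
    if not samples:
        raise ValueError(f"no samples from class {class_name!r}")
    taxa = metadata.frame.loc[samples, level]
    uniq = sorted(taxa.unique())
    if len(uniq) < 2:
        raise ValueError(f"class {class_name!r} has fewer than 2 taxa at level {level!r}")
    pres = table.select_samples(samples).presence()  # asv x sample
    codes = np.array([uniq.index(t) for t in taxa])
    inc = np.zeros((pres.shape[0], len(uniq)), dtype=np.int64)
    for k in range(len(uniq)):
        inc[:, k] = pres[:, codes == k].sum(axis=1)
    return pd.DataFrame(inc, index=table.asv_ids, columns=uniq)


def pielou_evenness(incidence, k: int | None = None) -> float:
    """Pielou's J of an incidence vector: Shannon entropy / ln(K).

    J = 0 when a single taxon holds all incidence; J = 1 when the incidence
    is perfectly even over all K taxa.  K defaults to the vector length.
    """
    v = np.asarray(incidence, dtype=float)
    if k is None:
        k = v.size
    if k < 2:
        raise ValueError("evenness needs at least 2 taxa")
    total = v.sum()
    if total <= 0:
        raise ValueError("zero-sum incidence vector")
    p = v / total
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.sum(np.where(p > 0, p * np.log(p), 0.0))
    return float(h / np.log(k))


def _evenness_rows(inc: np.ndarray, k: int) -> np.ndarray:
    """Row-wise Pielou J for an (n, K) incidence array with positive row sums."""
    totals = inc.sum(axis=1, keepdims=True)
    p = inc / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.sum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    return h / np.log(k)


def evenness_ses(
    table: FeatureTable,
    metadata: SampleMetadata,
    class_name: str,
    level: str = "host_order",
    n_perm: int = 100,
    min_samples: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pielou-evenness SES per ASV within one host class.

    Only ASVs present in at least ``min_samples`` of the class's samples are
    scored.  For each, the null redraws its occurrence count of samples
    uniformly without replacement from the class's samples, ``n_perm`` times,
    and SES = (J_obs - mean) / sd of the permuted J values.  A null sd of 0
    yields SES = NaN with ``undefined=True`` — never a silent 0.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    class_samples = [s for s in table.sample_ids if s in set(metadata.samples_of_class(class_name))]
    if not class_samples:
        raise ValueError(f"no samples from class {class_name!r}")
    taxa = metadata.frame.loc[class_samples, level]
    uniq = sorted(taxa.unique())
    k_taxa = len(uniq)
    if k_taxa < 2:
        raise ValueError(f"class {class_name!r} has fewer than 2 taxa at level {level!r}")
    codes = np.array([uniq.index(t) for t in taxa])
    n_samples = len(class_samples)
    pres = table.select_samples(class_samples).presence()
    occ = pres.sum(axis=1)

    rng = substream(seed, f"evenness_ses:{class_name}")
    rows = []
    for a, asv in enumerate(table.asv_ids):
        n_occ = int(occ[a])
        if n_occ < min_samples:
            continue
        inc_obs = np.bincount(codes[pres[a]], minlength=k_taxa)
        j_obs = _evenness_rows(inc_obs[None, :], k_taxa)[0]
        # n_perm independent draws of n_occ samples without replacement
        draws = rng.random((n_perm, n_samples)).argsort(axis=1)[:, :n_occ]
        drawn_codes = codes[draws]  # (n_perm, n_occ)
        inc_perm = np.zeros((n_perm, k_taxa), dtype=np.int64)
        for t in range(k_taxa):
            inc_perm[:, t] = (drawn_codes == t).sum(axis=1)
        j_perm = _evenness_rows(inc_perm, k_taxa)
        mu, sd = float(j_perm.mean()), float(j_perm.std(ddof=0))
        undefined = sd == 0.0
        ses = float("nan") if undefined else (j_obs - mu) / sd
        rows.append(
            {
                "asv_id": asv,
                "n_occurrences": n_occ,
                "j_obs": float(j_obs),
                "perm_mean": mu,
                "perm_sd": sd,
                "ses": ses,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(
        rows, columns=["asv_id", "n_occurrences", "j_obs", "perm_mean", "perm_sd", "ses", "undefined"]
    ).set_index("asv_id")


def log_risk_ratio(
    table: FeatureTable,
    metadata: SampleMetadata,
    cap: float = 3.0,
    numerator_class: str = "Mammalia",
    denominator_class: str = "Aves",
) -> pd.DataFrame:
    """Per-ASV log risk ratio of prevalence between two host classes.

    lrr = ln(prev_mammal / prev_bird) where both prevalences are positive;
    class-exclusive ASVs get +cap (mammal-only) or -cap (bird-only).  ASVs
    absent from both classes are excluded.
    """
    num_samples = [s for s in table.sample_ids if s in set(metadata.samples_of_class(numerator_class))]
    den_samples = [s for s in table.sample_ids if s in set(metadata.samples_of_class(denominator_class))]
    if not num_samples or not den_samples:
        raise ValueError("both classes need at least one sample")
    pres = table.presence()
    in_num = np.isin(table.sample_ids, num_samples)
    in_den = np.isin(table.sample_ids, den_samples)
    prev_num = pres[:, in_num].mean(axis=1)
    prev_den = pres[:, in_den].mean(axis=1)
    keep = (prev_num > 0) | (prev_den > 0)
    lrr = np.zeros(len(prev_num))
    both = (prev_num > 0) & (prev_den > 0)
    lrr[both] = np.log(prev_num[both] / prev_den[both])
    lrr[(prev_num > 0) & (prev_den == 0)] = cap
    lrr[(prev_num == 0) & (prev_den > 0)] = -cap
    lrr = np.clip(lrr, -cap, cap)
    frame = pd.DataFrame(
        {"prev_mammal": prev_num, "prev_bird": prev_den, "lrr": lrr},
        index=table.asv_ids,
    )
    return frame[keep]


def sample_mean_lrr(table: FeatureTable, records: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean LRR over the scored ASVs present in each sample.

    Samples containing no scored ASV get mean NaN with ``n_scored = 0`` —
    flagged missing rather than coerced to 0.
    """
    scored = [a for a in table.asv_ids if a in records.index]
    pres = table.select_asvs(scored).presence()  # scored asvs x samples
    lrr = records.loc[scored, "lrr"].to_numpy()
    n_scored = pres.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(n_scored > 0, (pres * lrr[:, None]).sum(axis=0) / np.maximum(n_scored, 1), np.nan)
    return pd.DataFrame(
        {"mean_lrr": means, "n_scored": n_scored.astype(int)}, index=table.sample_ids
    )
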