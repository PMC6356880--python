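"""RPM normalization, tissue-enrichment classification and qPCR analysis.

Expression is compared across tissues on reads-per-million (RPM) scale
(count / library total x 1e6, replicates of one tissue averaged after
normalization).  A miRNA is called ubiquitous when its tissue RPMs differ by
at most a small fold (default 3), and enriched in a tissue set when every
member tissue exceeds the mean of the remaining tissues by a large fold
(default 10), the set grown greedily from the top tissue so that "one or a
few" tissues qualify.  Relative qPCR quantification uses the delta-delta-Ct
method against the mean of two stable reference miRNAs, with a two-sample
t-test and Bonferroni adjustment across the batch of tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QPCRTable:
    """Cq values (miRNA x sample) with tissue labels and reference miRNAs."""

    cq: pd.DataFrame
    reference_ids: tuple[str, str]
    tissue_of: dict[str, str]

    def __post_init__(self) -> None:
        for ref in self.reference_ids:
            if ref not in self.cq.index:
                raise ValueError(f"reference miRNA {ref!r} missing from table")
        if not np.isfinite(self.cq.to_numpy(dtype=float)).all():
            raise ValueError("Cq values must be finite")


@dataclass
class EnrichmentResult:
    """Relative enrichment of one miRNA in a focal tissue."""

    mirna: str
    tissue: str
    ddct: float
    fold: float
    p_value: float | None
    significant: bool | None

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be > 0")


def rpm_normalize(
    counts: pd.DataFrame, tissue_of: dict[str, str] | None = None
) -> pd.DataFrame:
    """Reads-per-million normalization, then replicate averaging per tissue.

    ``counts`` is miRNA x sample.  When ``tissue_of`` maps sample to tissue,
    the returned matrix is miRNA x tissue with replicate RPM values averaged;
    otherwise columns are untouched samples.
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total samples: {bad}")
    rpm = counts / totals * 1e6
    if tissue_of is None:
        return rpm
    missing = [s for s in rpm.columns if s not in tissue_of]
    if missing:
        raise ValueError(f"samples without tissue label: {missing}")
    return rpm.T.groupby([tissue_of[s] for s in rpm.columns]).mean().T


def top_k(matrix: pd.DataFrame, k: int = 15) -> tuple[dict[str, list[str]], list[str]]:
    """Per-tissue top-k miRNA lists (descending value, ties by id) and their union."""
    if len(matrix.index) < k:
        raise ValueError(f"need at least {k} miRNAs, have {len(matrix.index)}")
    lists: dict[str, list[str]] = {}
    union: set[str] = set()
    for tissue in matrix.columns:
        order = sorted(
            matrix.index, key=lambda m: (-matrix.at[m, tissue], m)
        )
        lists[tissue] = order[:k]
        union.update(lists[tissue])
    return lists, sorted(union)


def classify_expression(
    matrix: pd.DataFrame,
    ubiquitous_fold: float = 3.0,
    enriched_fold: float = 10.0,
) -> pd.DataFrame:
    """Label each miRNA ubiquitous, tissue-enriched, or neither.

    Ubiquitous: max/min tissue value <= ``ubiquitous_fold`` (all tissues
    detected).  Enriched in tissue set S: every value in S exceeds
    ``enriched_fold`` times the mean of the values outside S, with S the
    smallest abundance-ordered prefix of tissues satisfying the condition —
    so a miRNA strongly shared by two tissues (e.g. muscle and heart) is
    called enriched in both.
    """
    if len(matrix.columns) < 2:
        raise ValueError("need at least two tissues")
    rows = []
    for mirna in matrix.index:
        values = matrix.loc[mirna]
        label, tissues = "neither", ()
        if values.min() > 0 and values.max() / values.min() <= ubiquitous_fold:
            label = "ubiquitous"
        else:
            order = sorted(
                matrix.columns, key=lambda t: (-values[t], t)
            )
            chosen: list[str] = []
            for size in range(1, len(order)):
                candidate = order[:size]
                outside = values[order[size:]]
                if outside.mean() > 0 and values[candidate].min() > enriched_fold * outside.mean():
                    chosen = candidate
                    break
            if chosen:
                label, tissues = "enriched", tuple(chosen)
        rows.append(
            {"mirna": mirna, "label": label, "tissues": ",".join(tissues)}
        )
    return pd.DataFrame(rows).set_index("mirna")


def diversity_and_proportions(
    counts: pd.DataFrame,
    detect_min: int = 1,
    families: dict[str, list[str]] | None = None,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame | None]:
    """Per-stage miRNA diversity and per-miRNA abundance proportions.

    Diversity counts miRNAs with raw count >= ``detect_min`` per stage;
    proportions divide each miRNA's count by the stage total.  Family
    proportions sum the listed members.
    """
    diversity = (counts >= detect_min).sum(axis=0)
    totals = counts.sum(axis=0)
    proportions = counts / totals
    family_props = None
    if families:
        family_props = pd.DataFrame(
            {
                name: proportions.reindex(members).fillna(0.0).sum(axis=0)
                for name, members in families.items()
            }
        ).T
    return diversity, proportions, family_props


def ddct(
    qpcr: QPCRTable,
    mirna: str,
    focal_tissue: str,
    n_tests: int = 1,
) -> EnrichmentResult:
    """Delta-delta-Ct enrichment of one miRNA in a focal tissue.

    Per sample, dCt = Cq(target) - mean(Cq of the two references); ddCt is
    the mean dCt in the focal tissue minus the mean dCt over all other
    samples pooled; fold change = 2**(-ddCt).  A two-sample t-test on the
    per-sample dCt values is Bonferroni-adjusted by ``n_tests``; p is None
    (and significance unassessed) when either group has fewer than two
    samples.
    """
    if mirna not in qpcr.cq.index:
        raise KeyError(f"miRNA {mirna!r} not in Cq table")
    samples = list(qpcr.cq.columns)
    focal = [s for s in samples if qpcr.tissue_of[s] == focal_tissue]
    others = [s for s in samples if qpcr.tissue_of[s] != focal_tissue]
    if not focal or not others:
        raise ValueError("need the focal tissue and at least one other")
    ref_mean = qpcr.cq.loc[list(qpcr.reference_ids)].mean(axis=0)
    dct = qpcr.cq.loc[mirna] - ref_mean
    ddct_value = float(dct[focal].mean() - dct[others].mean())
    fold = 2.0 ** (-ddct_value)
    p_value: float | None = None
    significant: bool | None = None
    if len(focal) >= 2 and len(others) >= 2:
        _, p = stats.ttest_ind(dct[focal], dct[others])
        p_value = float(p)
        significant = min(1.0, p_value * n_tests) <= 0.05
    return EnrichmentResult(
        mirna=mirna,
        tissue=focal_tissue,
        ddct=ddct_value,
        fold=fold,
        p_value=p_value,
        significant=significant,
    )


def fold_from_ddct(ddct_value: float) -> int:
    """Integer-reported fold change, 2**(-ddCt) rounded to the nearest whole."""
    return round(2.0 ** (-ddct_value))


def load_qpcr_reference() -> pd.DataFrame:
    """Bundled tissue-enrichment qPCR reference rows (ddCt and printed fold)."""
    path = resources.files("mirforge.data").joinpath("qpcr_enrichment.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")
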