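"""Published reference values for the CHARLS 2018 multimorbidity cohort.

The CHARLS 2018 chronic-disease cohort itself is available only on request,
but the study that benchmarked dynamic link prediction on it published the
per-disease patient counts (cohort of 3,333 multimorbid patients, 14 chronic
disease categories) and a five-model MAP/MRR comparison table.  Those printed
numbers are inputs here: the prevalence percentages and the improvement
deltas over the second-best model are *recomputed* from them, never stored.
"""

from __future__ import annotations

import pandas as pd

from .cohort import DiseaseCatalog, prevalence_from_counts

CHARLS_COHORT_SIZE = 3333

#: Published patient counts per chronic-disease category (descending).
CHARLS_PREVALENCE_COUNTS: dict[str, int] = {
    "Dyslipidemia": 1235,
    "Hypertension": 1193,
    "Stomach or other digestive diseases": 892,
    "Heart attack, coronary heart disease, angina, or other heart problems": 864,
    "Arthritis or rheumatism": 799,
    "Diabetes or high blood sugar": 681,
    "Chronic lung diseases": 639,
    "Stroke": 611,
    "Kidney disease": 489,
    "Liver disease": 417,
    "Memory-related disease": 325,
    "Asthma": 317,
    "Emotional, nervous, or psychiatric problems": 168,
    "Cancer or malignant tumor": 147,
}

#: Published benchmark MAP/MRR of five models on the CHARLS 2018 network.
BENCHMARK_METRICS: dict[str, dict[str, float]] = {
    "GCN": {"MAP": 0.3891, "MRR": 0.2980},
    "GCN-LSTM": {"MAP": 0.4304, "MRR": 0.2000},
    "EvolveGCN": {"MAP": 0.3619, "MRR": 0.3112},
    "Graphormer": {"MAP": 0.4257, "MRR": 0.2500},
    "CE-GCN": {"MAP": 0.4387, "MRR": 0.3733},
}


#: Short machine-friendly keys for the disease categories above.
SHORT_NAMES: dict[str, str] = {
    "Dyslipidemia": "dyslipidemia",
    "Hypertension": "hypertension",
    "Stomach or other digestive diseases": "digestive_disease",
    "Heart attack, coronary heart disease, angina, or other heart problems": "heart_disease",
    "Arthritis or rheumatism": "arthritis",
    "Diabetes or high blood sugar": "diabetes",
    "Chronic lung diseases": "chronic_lung_disease",
    "Stroke": "stroke",
    "Kidney disease": "kidney_disease",
    "Liver disease": "liver_disease",
    "Memory-related disease": "memory_disease",
    "Asthma": "asthma",
    "Emotional, nervous, or psychiatric problems": "psychiatric_problems",
    "Cancer or malignant tumor": "cancer",
}


def charls_catalog() -> DiseaseCatalog:
    """The 14-disease catalog, ordered by published prevalence (descending)."""
    return DiseaseCatalog(tuple(CHARLS_PREVALENCE_COUNTS))


def charls_prevalence() -> pd.DataFrame:
    """Prevalence table recomputed from published counts and cohort size."""
    return prevalence_from_counts(CHARLS_PREVALENCE_COUNTS, CHARLS_COHORT_SIZE)


def benchmark_table() -> pd.DataFrame:
    """The published five-model MAP/MRR comparison as a DataFrame."""
    return pd.DataFrame(BENCHMARK_METRICS).T.rename_axis("model").reset_index()


def improvement_over_second_best(metric: str) -> float:
    """CE-GCN's margin over the best competing model on ``metric``.

    Computed from the benchmark table at call time: CE-GCN value minus the
    maximum over the other four models.
    """
    ours = BENCHMARK_METRICS["CE-GCN"][metric]
    others = max(v[metric] for k, v in BENCHMARK_METRICS.items() if k != "CE-GCN")
    return round(ours - others, 4)
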