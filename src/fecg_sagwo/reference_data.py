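"""Published benchmark detection counts for the two clinical datasets.

The Labour (12 records x 5 min) and Pregnancy (10 records x 20 min)
abdominal-ECG collections (figshare, doi:10.6084/m9.figshare.c.4740794)
are the standard real-data benchmark for this extraction method.  The
raw recordings are an optional download and never a build dependency;
what is embedded here are only the published per-record TP/FP/FN
matching counts, from which all derived percentages (ACC, SE, PPV, F1
and their dataset means) can be recomputed with
:func:`fecg_sagwo.evaluation.compute_metrics`.
"""

from __future__ import annotations

__all__ = ["LABOUR_COUNTS", "PREGNANCY_COUNTS", "dataset_mean_metrics"]

# record id -> (TP, FP, FN)
LABOUR_COUNTS: dict[str, tuple[int, int, int]] = {
    "r01": (640, 5, 4),
    "r02": (612, 5, 25),
    "r03": (547, 225, 169),
    "r04": (671, 13, 10),
    "r05": (653, 7, 7),
    "r06": (676, 6, 8),
    "r07": (619, 10, 13),
    "r08": (644, 0, 1),
    "r09": (666, 9, 8),
    "r10": (627, 0, 0),
    "r11": (640, 10, 6),
    "r12": (655, 3, 2),
}

PREGNANCY_COUNTS: dict[str, tuple[int, int, int]] = {
    "r01": (3101, 19, 17),
    "r02": (2684, 51, 107),
    "r03": (2461, 21, 96),
    "r04": (2760, 6, 14),
    "r05": (2762, 7, 2),
    "r06": (2814, 102, 65),
    "r07": (2962, 117, 134),
    "r08": (2864, 64, 33),
    "r09": (2787, 39, 29),
    "r10": (2427, 175, 156),
}


def dataset_mean_metrics(counts: dict[str, tuple[int, int, int]]) -> dict[str, float]:
    """Unweighted per-record means of ACC/SE/PPV/F1 over a dataset."""
    from .evaluation import compute_metrics

    stats = [compute_metrics(*c) for c in counts.values()]
    n = len(stats)
    return {
        "acc": sum(s.acc for s in stats) / n,
        "se": sum(s.se for s in stats) / n,
        "ppv": sum(s.ppv for s in stats) / n,
        "f1": sum(s.f1 for s in stats) / n,
    }
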