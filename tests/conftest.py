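import numpy as np
import pytest

from eaemap.scores import ALIVE, CohortTable, MouseMeta, ScoreSeries


def make_series(
    classic,
    ar=None,
    window=(5, 50),
    status=None,
    mouse_id="m1",
    strain="CC001",
    sex="F",
    cohort="C1",
):
    """Build a ScoreSeries from per-day score lists padded with zeros."""
    lo, hi = window
    n = hi - lo + 1
    c = np.zeros(n, dtype=int)
    c[: len(classic)] = classic
    a = np.zeros(n, dtype=int)
    if ar is not None:
        a[: len(ar)] = ar
    st = np.array([ALIVE] * n, dtype=object)
    if status is not None:
        st[: len(status)] = status
    return ScoreSeries(
        mouse=MouseMeta(mouse_id, strain, sex, cohort),
        days=np.arange(lo, hi + 1),
        classic=c,
        ar=a,
        status=st,
    )


def series_at_days(day_scores, window=(5, 50), channel="classic", **kw):
    """ScoreSeries with {day: score} on one channel, zeros elsewhere."""
    lo, hi = window
    n = hi - lo + 1
    arr = np.zeros(n, dtype=int)
    for d, s in day_scores.items():
        arr[d - lo] = s
    if channel == "classic":
        return make_series(arr, window=window, **kw)
    return make_series(np.zeros(n, dtype=int), ar=arr, window=window, **kw)


@pytest.fixture
def tiny_cohort():
    return CohortTable(
        series=[
            make_series([0] * 46, mouse_id="a"),
            make_series([0] * 46, mouse_id="b"),
        ]
    )
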