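"""Scatter + fitted-curve plots for QSPR fits (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

from .qspr import QSPRResults


def plot_fit(results: QSPRResults, path: str, n_curve: int = 200) -> None:
    """Write a scatter of the data with the fitted polynomial curve to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rm = results.regression_model
    x = results.model.exog
    y = results.model.endog
    grid = np.linspace(x.min(), x.max(), n_curve)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, color="tab:blue", label="observed")
    deg = "linear" if rm.degree == 1 else "quadratic"
    ax.plot(grid, rm.predict(grid), color="tab:red",
            label=f"{deg} fit (R$^2$={rm.r_squared:.4f})")
    ax.set_xlabel(rm.index_name or "TI")
    ax.set_ylabel(rm.property_name or "P")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
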