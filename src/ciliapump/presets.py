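"""Registry of published-figure parameter presets.

Each entry records the parameter values printed in the source figure
captions, plus the swept quantity.  Where a caption does not print the
legend's value list (the epsilon list of fig2b, the alpha/beta/delta_p/
Qbar lists of figs 3, 4b, 5, 7, 9), the ``sweep`` list here is a
documented reconstruction chosen to bracket the caption's fixed values —
those lists are package defaults, not published facts, and can be
overridden at the call site.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FIGURE_PRESETS", "figure_ids"]

_QBAR_GRID = tuple(np.round(np.linspace(-1.0, 2.0, 31), 6))
_EPS_GRID = tuple(np.round(np.linspace(0.0, 0.35, 36), 6))
_ALPHA_GRID = tuple(np.round(np.linspace(0.0, 1.0, 26), 6))
_BETA_GRID = tuple(np.round(np.linspace(0.05, 1.0, 20), 6))
_Z_GRID = tuple(np.round(np.linspace(0.0, 1.0, 201), 6))

FIGURE_PRESETS = {
    # pressure rise vs mean flow rate
    "fig2a": dict(kind="pump_curve", base=dict(epsilon=0.25, alpha=0.4, beta=0.4),
                  sweep=("hp", (0.0, 0.01, 0.05, 0.09)), qbar=_QBAR_GRID),
    "fig2b": dict(kind="pump_curve", base=dict(hp=0.09, alpha=0.4, beta=0.4),
                  sweep=("epsilon", (0.20, 0.25, 0.30)),  # reconstructed
                  qbar=_QBAR_GRID),
    "fig3a": dict(kind="pump_curve", base=dict(hp=0.09, epsilon=0.25, beta=0.4),
                  sweep=("alpha", (0.0, 0.2, 0.4, 0.6)),  # reconstructed
                  qbar=_QBAR_GRID),
    "fig3b": dict(kind="pump_curve", base=dict(hp=0.09, epsilon=0.25, alpha=0.4),
                  sweep=("beta", (0.2, 0.4, 0.6)),        # reconstructed
                  qbar=_QBAR_GRID),
    # mean flow rate vs cilia length
    "fig4a": dict(kind="flow_vs_eps", base=dict(alpha=0.4, beta=0.4),
                  drive=dict(delta_p=-5.5),
                  sweep=("hp", (0.0, 0.01, 0.03, 0.05, 0.09)),
                  eps=_EPS_GRID),
    "fig4b": dict(kind="flow_vs_eps", base=dict(alpha=0.4, beta=0.4, hp=0.03),
                  sweep=("delta_p", (0.0, -2.0, -4.0, -5.5)),  # reconstructed
                  eps=_EPS_GRID),
    # mean flow rate vs alpha / beta
    "fig5a": dict(kind="flow_vs_param", base=dict(epsilon=0.25, beta=0.4),
                  drive=dict(delta_p=-5.5), param=("alpha", _ALPHA_GRID),
                  sweep=("hp", (0.0, 0.01, 0.05, 0.09))),
    "fig5b": dict(kind="flow_vs_param", base=dict(epsilon=0.25, alpha=0.4),
                  drive=dict(delta_p=-5.5), param=("beta", _BETA_GRID),
                  sweep=("hp", (0.0, 0.01, 0.05, 0.09))),
    # axial pressure gradient profiles
    "fig6a": dict(kind="dpdz_profile", base=dict(epsilon=0.2, alpha=0.4, beta=0.4),
                  drive=dict(qbar=0.95),
                  sweep=("hp", (0.0, 0.01, 0.05, 0.09)), z=_Z_GRID),
    "fig6b": dict(kind="dpdz_profile", base=dict(hp=0.05, alpha=0.4, beta=0.4),
                  drive=dict(qbar=0.95),
                  sweep=("epsilon", (0.15, 0.20, 0.25)),  # reconstructed
                  z=_Z_GRID),
    "fig7": dict(kind="dpdz_profile", base=dict(hp=0.05, epsilon=0.25,
                                                alpha=0.4, beta=0.4),
                 sweep=("qbar", (0.2, 0.4, 0.6, 0.8, 1.0)),  # reconstructed
                 z=_Z_GRID),
    # axial velocity profiles at z = 1
    "fig8a": dict(kind="velocity_profile", base=dict(epsilon=0.25, alpha=0.4,
                                                     beta=0.4),
                  drive=dict(qbar=0.95), z=1.0,
                  sweep=("hp", (0.0, 0.01, 0.05, 0.09))),
    "fig8b": dict(kind="velocity_profile", base=dict(hp=0.05, alpha=0.4,
                                                     beta=0.4),
                  drive=dict(qbar=0.95), z=1.0,
                  sweep=("epsilon", (0.05, 0.15, 0.25, 0.35))),
    "fig9a": dict(kind="velocity_profile", base=dict(hp=0.05, epsilon=0.25,
                                                     beta=0.4),
                  drive=dict(qbar=0.95), z=1.0,
                  sweep=("alpha", (0.0, 0.4, 0.8))),       # reconstructed
    "fig9b": dict(kind="velocity_profile", base=dict(hp=0.05, epsilon=0.25,
                                                     alpha=0.4, beta=0.4),
                  z=1.0,
                  sweep=("qbar", (0.6, 0.8, 0.95, 1.1))),  # reconstructed
    # streamline / trapping panels
    "fig10": dict(kind="streamlines", base=dict(epsilon=0.25, alpha=0.4,
                                                beta=0.4),
                  drive=dict(qbar=0.95),
                  sweep=("hp", (0.0, 0.01, 0.05, 0.09))),
    "fig11": dict(kind="streamlines", base=dict(hp=0.05, alpha=0.4, beta=0.4),
                  drive=dict(qbar=0.95),
                  sweep=("epsilon", (0.05, 0.15, 0.25, 0.35))),
}


def figure_ids() -> list[str]:
    return sorted(FIGURE_PRESETS)
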