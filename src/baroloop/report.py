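"""Assembly of the equilibrium-diagram report bundle.

A report bundle combines, for one MN arc and a pair of NM arcs (the
pre- and post-tilt plant lines): both closed-loop operating points, the
disturbance decomposition (closed-loop vs open-loop pressure fall,
attenuation ratio, implied loop gain), and the slope-preserving
parallel-shift counterfactual under which the implied loop gain equals
the true product of arc gains exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

from . import __version__
from .core import (
    MNArcParams,
    NMArcParams,
    open_loop_gain,
    parallel_shift_counterfactual,
    solve_operating_point,
    tilt_disturbance_report,
)


def build_report_bundle(
    mn: MNArcParams,
    nm_pre: NMArcParams,
    nm_post: NMArcParams,
    provenance: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Compute the full disturbance report for one tilt transition.

    Returns a plain nested dictionary (dataclasses included) suitable for
    :func:`baroloop.io.write_report_json`.
    """
    op_pre = solve_operating_point(mn, nm_pre)
    op_post = solve_operating_point(mn, nm_post)
    disturbance = tilt_disturbance_report(mn, nm_pre, nm_post)
    counterfactual = parallel_shift_counterfactual(mn, nm_pre, nm_post)
    return {
        "version": __version__,
        "parameters": {
            "mn": dataclasses.asdict(mn),
            "nm_pre": dataclasses.asdict(nm_pre),
            "nm_post": dataclasses.asdict(nm_post),
        },
        "operating_points": {"pre": op_pre, "post": op_post},
        "open_loop_gain_pre": open_loop_gain(mn, nm_pre),
        "open_loop_gain_post": open_loop_gain(mn, nm_post),
        "disturbance": disturbance,
        "parallel_shift_counterfactual": counterfactual,
        "provenance": provenance or {},
    }


def plot_equilibrium_diagram(
    mn: MNArcParams,
    nm_pre: NMArcParams,
    nm_post: NMArcParams,
    out_path: str | Path,
) -> Path:
    """Draw the equilibrium diagram on the PNE-AP plane and save it.

    Shows the MN line and both NM lines, with the pre-tilt operating point
    (Point 1), the post-tilt operating point (Point 2), and the open-loop
    point reached if the reflex froze at the pre-tilt norepinephrine level
    (Point 3).  Vector formats (SVG, PDF) are preserved as-is by the
    matplotlib backend chosen from the file suffix.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .core import nm_arc_response

    op_pre = solve_operating_point(mn, nm_pre)
    op_post = solve_operating_point(mn, nm_post)
    open_loop_ap = nm_arc_response(op_pre.pne, nm_post)

    pne_max = max(op_pre.pne, op_post.pne, 1.0) * 1.6
    pne = [0.0, pne_max]

    fig, ax = plt.subplots(figsize=(6, 5))
    mn_ap = [mn.ap_mn0, mn.ap_mn0 - pne_max / mn.g_mn] if mn.g_mn else [mn.ap_mn0] * 2
    ax.plot(pne, mn_ap, "-", color="k", label="MN arc", gid="mn-arc")
    ax.plot(
        pne, [nm_arc_response(p, nm_pre) for p in pne],
        ":", color="tab:blue", label="NM arc (pre)", gid="nm-arc-pre",
    )
    ax.plot(
        pne, [nm_arc_response(p, nm_post) for p in pne],
        "--", color="tab:red", label="NM arc (post)", gid="nm-arc-post",
    )
    for label, (x, y) in {
        "Point 1": (op_pre.pne, op_pre.ap),
        "Point 2": (op_post.pne, op_post.ap),
        "Point 3": (op_pre.pne, open_loop_ap),
    }.items():
        ax.plot([x], [y], "o", color="k", gid=label.lower().replace(" ", "-"))
        ax.annotate(label, (x, y), textcoords="offset points", xytext=(6, 6))
    ax.set_xlabel("Plasma norepinephrine (pg/ml)")
    ax.set_ylabel("Arterial pressure (mmHg)")
    ax.set_title("Baroreflex equilibrium diagram")
    ax.legend(loc="best")
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
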