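"""Bundled reference tables from the published Texas cancer registry study.

Small published summary tables used as worked-example inputs and as fixed
inputs to the reproduction script: site-specific case counts for digestive
and respiratory cancers in Texas 2000-2008, and the posterior mean Hispanic
disparity coefficients (delta, on the log relative-risk scale) reported for
the three model variants.  These are published aggregates, not the
IRB-restricted record-level registry file.
"""

from __future__ import annotations

import pandas as pd

# site-specific case counts, Texas Cancer Registry 2000-2008
_SITE_COUNTS = [
    ("digestive", "Gum and mouth", 506),
    ("digestive", "Esophagus", 7745),
    ("digestive", "Stomach", 14190),
    ("digestive", "Small intestine", 4183),
    ("digestive", "Colon and rectum", 85821),
    ("digestive", "Anus, anal canal and anorectum", 2876),
    ("digestive", "Liver", 14032),
    ("digestive", "Gallbladder", 2095),
    ("digestive", "Other biliary", 2702),
    ("digestive", "Pancreas", 19124),
    ("digestive", "Retroperitoneum", 780),
    ("digestive", "Peritoneum, omentum and mesentery", 1026),
    ("digestive", "Other digestive organs", 572),
    ("respiratory", "Nose, nasal cavity and middle ear", 1469),
    ("respiratory", "Larynx", 7720),
    ("respiratory", "Lung and bronchus", 113357),
    ("respiratory", "Pleura", 1295),
    ("respiratory", "Trachea, mediastinum and other respiratory organs", 596),
]

# posterior mean disparity coefficient delta per (model variant, cancer)
_DISPARITY_COEFFICIENTS = {
    (1, "digestive"): 0.052,
    (2, "digestive"): 0.138,
    (3, "digestive"): 0.152,
    (1, "respiratory"): 0.107,
    (2, "respiratory"): 0.146,
    (3, "respiratory"): 0.152,
}


def texas_site_counts() -> pd.DataFrame:
    """Site-level case counts by body system (columns system, site, count)."""
    return pd.DataFrame(_SITE_COUNTS, columns=["system", "site", "count"])


def reference_disparity_coefficients() -> pd.DataFrame:
    """Reported posterior mean disparity coefficients per model and cancer."""
    rows = [
        {"model": m, "cancer": c, "delta": d}
        for (m, c), d in _DISPARITY_COEFFICIENTS.items()
    ]
    return pd.DataFrame(rows)
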