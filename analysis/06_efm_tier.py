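"""Full EFM tier for e_coli_core (long-running).

Enumerates all elementary flux modes of the e_coli_core network with the
exact double description method and reduces them to unique boundary
exchange patterns.  Expected counts: 100,274 EFMs, reducing to 1,004
unique patterns of which 738 support growth.  Exact rational DD on a
141-column split network takes orders of magnitude longer than the ECM
route (hours rather than seconds in this implementation) — run the ECM
tier (03_e_coli_core.py) unless the full EFM set itself is needed.
"""

import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from exopath.efm import enumerate_efms, pattern_vectors
from exopath.network import load_e_coli_core, standardize
from exopath.patterns import filter_growth, to_patterns


def main():
    net = load_e_coli_core()
    std = standardize(net)
    t0 = time.perf_counter()
    efms = enumerate_efms(std, max_rays=5_000_000)
    print(f"EFMs: {efms.count} in {time.perf_counter() - t0:.0f}s")
    vecs, bio = pattern_vectors(efms, std)
    coll = to_patterns(vecs, std, definition="EFM", biomass_fluxes=bio)
    print(f"unique patterns: {coll.count}")
    print(f"growth-supporting: {filter_growth(coll).count}")


if __name__ == "__main__":
    main()
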