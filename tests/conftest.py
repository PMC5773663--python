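"""Shared fixtures: a tiny hand-built taxonomy and hit sets with known outcomes."""
import io

import pytest

from metrs.contxt import HitSet
from metrs.taxonomy import parse_taxonomy_tsv

_LACTO = "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus"
_CANDIDA = "Eukaryota;Ascomycota;Saccharomycetes;Saccharomycetales;Saccharomycetaceae;Candida"

TOY_TAXONOMY_TSV = f"""\
# tiny two-domain fixture
E1\t{_LACTO};Lactobacillus rhamnosus
E2\t{_LACTO};Lactobacillus rhamnosus
E3\t{_LACTO};Lactobacillus rhamnosus
E4\t{_LACTO};Lactobacillus rhamnosus
E5\t{_LACTO};Lactobacillus casei
E6\t{_LACTO};Lactobacillus gasseri
E7\t{_CANDIDA};Candida albicans
E8\t{_CANDIDA}
"""


@pytest.fixture(scope="session")
def toy_db():
    return parse_taxonomy_tsv(io.StringIO(TOY_TAXONOMY_TSV), name="toy")


@pytest.fixture(scope="session")
def four_read_hitsets():
    """Four reads whose consensus outcomes are species, species, genus, unknown."""
    return [
        HitSet("r1", frozenset({"E1"})),                            # single hit
        HitSet("r2", frozenset({"E1", "E2", "E3", "E4", "E5"})),    # 4/5 = 0.8
        HitSet("r3", frozenset({"E1", "E2", "E3", "E5", "E6"})),    # 3/5 = 0.6 -> genus
        HitSet("r4", frozenset({"E1", "E7"})),                      # 50/50 domains
    ]
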