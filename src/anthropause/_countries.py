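"""Country-code registry used for occurrence filtering and aggregation.

Occurrences are aggregated by the country code carried on the record (the
convention of the big occurrence aggregators), never re-derived from
coordinates.  The recognised universe is the 249 officially assigned
ISO 3166-1 alpha-2 codes plus two conventional extensions: ``XK`` (Kosovo)
and ``ZZ`` (high seas / international waters), 251 administrative units in
total.
"""

from __future__ import annotations

# The 249 officially assigned ISO 3166-1 alpha-2 codes.
ISO_3166_1_ALPHA2: frozenset[str] = frozenset("""
AD AE AF AG AI AL AM AO AQ AR AS AT AU AW AX AZ
BA BB BD BE BF BG BH BI BJ BL BM BN BO BQ BR BS BT BV BW BY BZ
CA CC CD CF CG CH CI CK CL CM CN CO CR CU CV CW CX CY CZ
DE DJ DK DM DO DZ
EC EE EG EH ER ES ET
FI FJ FK FM FO FR
GA GB GD GE GF GG GH GI GL GM GN GP GQ GR GS GT GU GW GY
HK HM HN HR HT HU
ID IE IL IM IN IO IQ IR IS IT
JE JM JO JP
KE KG KH KI KM KN KP KR KW KY KZ
LA LB LC LI LK LR LS LT LU LV LY
MA MC MD ME MF MG MH MK ML MM MN MO MP MQ MR MS MT MU MV MW MX MY MZ
NA NC NE NF NG NI NL NO NP NR NU NZ
OM
PA PE PF PG PH PK PL PM PN PR PS PT PW PY
QA
RE RO RS RU RW
SA SB SC SD SE SG SH SI SJ SK SL SM SN SO SR SS ST SV SX SY SZ
TC TD TF TG TH TJ TK TL TM TN TO TR TT TV TW TZ
UA UG UM US UY UZ
VA VC VE VG VI VN VU
WF WS
YE YT
ZA ZM ZW
""".split())

#: Kosovo (user-assigned, in wide de-facto use by data aggregators).
KOSOVO = "XK"
#: High seas / international waters pseudo-code.
HIGH_SEAS = "ZZ"

#: Full recognised universe: 251 administrative units.
COUNTRY_CODES: frozenset[str] = ISO_3166_1_ALPHA2 | {KOSOVO, HIGH_SEAS}

#: The four-level economic development classification, in its conventional
#: order.  "developed" is the reference level throughout the modelling code.
ECONOMIC_CLASSES: tuple[str, ...] = (
    "developed",
    "emerging",
    "developing",
    "least_developed",
)
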