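"""The six behaviours the model optimises over, indexed 1-6.

1 and 2 are the two foraging intensities (high gain / high risk versus lower
gain / lower risk), 3 is resting in a predator-safe spot, and 4-6 manipulate
the hypothermic state (deepen, rewarm, hold).
"""

FORAGE_HIGH = 1   #: intensive foraging
FORAGE_LOW = 2    #: cautious foraging
REST = 3          #: rest in predator-safe habitat
COOL = 4          #: enter, or go deeper into, hypothermia
WARM = 5          #: raise body temperature
HOLD = 6          #: stay at the current hypothermic depth

ALL = (FORAGE_HIGH, FORAGE_LOW, REST, COOL, WARM, HOLD)

#: evaluation order used for tie-breaking in the policy: lower predation
#: risk first (rest < cautious < intensive < hypothermic classes in
#: daylight; at night the classes are constant so index order decides),
#: then lower behaviour index.
TIE_BREAK_ORDER = (REST, FORAGE_LOW, FORAGE_HIGH, COOL, WARM, HOLD)

NAMES = {
    FORAGE_HIGH: "forage_high",
    FORAGE_LOW: "forage_low",
    REST: "rest",
    COOL: "cool",
    WARM: "warm",
    HOLD: "hold",
}
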