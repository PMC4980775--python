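"""A fixed, versioned list of English function words.

Stop-words are removed from the token sequence before windows are built, so
that the classifier's context slots carry content words (in the running
example "Thalidomide inhibited the formation", the window around
"inhibited" sees "Thalidomide" and "formation" once "the" is dropped).
"""

STOPWORDS: frozenset[str] = frozenset(
    """
    a an the this that these those
    and or but nor so yet
    of in on at by for with from to into onto over under between among
    as about against during through after before above below up down out off
    is am are was were be been being
    do does did have has had having
    it its he she his her they them their we our you your i my me us
    not no than then there here when where which who whom whose what
    will would can could shall should may might must
    """.split()
)
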