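"""Hand-verified golden cases for the scanning refinement.

Each pair is (input track, expected refined track), derived by applying
the two rules by hand under the single left-to-right pass semantics:
a '2' flips to '1' after a working-track run of >=5 '1's when followed
by <=3 original '2's; a '1' flips to '2' after >=5 '2's when followed
by <=2 original '1's; flips cascade into the preceding-run measurement.
"""

GOLDEN_TRACKS = [
    # lone misprediction inside a long opposite run
    ("1111121111", "1111111111"),
    ("2222212222", "2222222222"),
    # alternating track: no preceding run ever reaches 5
    ("12121212", "12121212"),
    # fixpoints
    ("1111111111", "1111111111"),
    ("2222222222", "2222222222"),
    ("1", "1"),
    ("2", "2"),
    # trailing '2' run of 4 after >=5 '1's is absorbed by the cascade
    ("111112222", "111111111"),
    # ... but a run of 5 survives (following-run bound is <=3)
    ("1111122222", "1111122222"),
    # '1' run of 2 after >=5 '2's is erased
    ("2222211222", "2222222222"),
    # '1' run of 3 after >=5 '2's is erased (cascade)
    ("22222111222", "22222222222"),
    # '1' run of 4 survives (following-run bound is <=2)
    ("222221111222", "222221111222"),
    # preceding run of only 4: no rule fires
    ("111121111", "111121111"),
    ("211112111", "211112111"),
    # '2' run of 2 inside '1's: both flipped
    ("1111122111", "1111111111"),
    # two short '2' runs; the trailing run of 3 at track end also absorbed
    ("111112211222", "111111111111"),
    # long runs on both sides: interiors and boundaries all stable
    ("221111122222211111", "221111122222211111"),
    ("111111222222111111", "111111222222111111"),
    # '2' run of exactly 5 after 5 '1's: stable
    ("21111122222", "21111122222"),
    # '1' run of 4 after 5 '2's at track end: stable
    ("12222211111", "12222211111"),
    # short runs everywhere: nothing reaches the preceding-run bound
    ("1211121112", "1211121112"),
    # lone codes at the track end
    ("111112", "111111"),
    ("222221", "222222"),
    # two lone '2's separated by long '1' runs
    ("111112111121", "111111111111"),
    # '2' run of 4 between long '1' runs is absorbed
    ("11111222211111", "11111111111111"),
    # '2' run of 5 between long '1' runs survives
    ("111112222211111", "111112222211111"),
    # isolated '1' after 5 '2's then 5 '1's: the lone '1' is erased, and the
    # following '1' run afterwards starts fresh from a preceding '2' run of 6
    ("222221222221", "222222222222"),
]
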