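# Synthetic stand-in lyric/art phrase list (one literal phrase per line).
# The phrase list used in the original study is unpublished, so this file
# ships invented song-like lines containing the collection keywords; the
# rule filter matches them case-insensitively as literal substrings.
lonely rivers flow to the neon sea
so lonely under the midnight chrome sky
loneliness is a highway painted silver
dancing lonely in the static rain
my lonely heart hums an empty chord
the loneliness waltz plays on and on
lonely satellites drifting past my window
queen of loneliness in a paper crown
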