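# QWERTY touch-keyboard layout in the style of a ~2012 4-inch-class phone,
# portrait orientation. Coordinates are millimetres, origin at the
# bottom-left of the screen, y up. Key geometry is a measured approximation
# of the pictured layout (exact dimensions are not published); pitch and key
# size are exposed here so they can be adjusted.
#
# Each layer has four rows listed top to bottom; `home: true` marks the row
# whose middle key ("G" on the letters layer) anchors the curvature,
# rotation and vertical-location transforms. Row entries are either a
# single-character key (span 1) or a mapping {id, kind, span} for wide or
# function keys. The spacebar (span 5) is modelled as 4 adjacent subkeys.
screen: {width: 51.0, height: 76.0}
pitch: {x: 4.9, y: 8.0}
key: {width: 4.6, height: 7.0}

layers:
  letters:
    rows:
      - [q, w, e, r, t, y, u, i, o, p]
      - home: true
        keys: [a, s, d, f, g, h, j, k, l]
      - - {id: shift, kind: shift, span: 1.5}
        - z
        - x
        - c
        - v
        - b
        - n
        - m
        - {id: backspace, kind: backspace, span: 1.5}
      - - {id: "123", kind: function, span: 2.5}
        - {id: space, kind: spacebar, span: 5.0}
        - {id: return, kind: return, span: 2.5}
  numbers:
    rows:
      - ["1", "2", "3", "4", "5", "6", "7", "8", "9", "0"]
      - home: true
        keys: ["-", "/", ":", ";", "(", ")", "$", "&", "@", '"']
      - - {id: "#+=", kind: function, span: 2.0}
        - {id: ".", kind: character, span: 1.2}
        - {id: ",", kind: character, span: 1.2}
        - {id: "?", kind: character, span: 1.2}
        - {id: "!", kind: character, span: 1.2}
        - {id: "'", kind: character, span: 1.2}
        - {id: backspace, kind: backspace, span: 2.0}
      - - {id: ABC, kind: function, span: 2.5}
        - {id: space, kind: spacebar, span: 5.0}
        - {id: return, kind: return, span: 2.5}
  symbols:
    rows:
      - ["[", "]", "{", "}", "#", "%", "^", "*", "+", "="]
      - home: true
        keys: ["_", "\\", "|", "~", "<", ">", "€", "£", "¥", "•"]
      - - {id: "123", kind: function, span: 2.0}
        - {id: ".", kind: character, span: 1.2}
        - {id: ",", kind: character, span: 1.2}
        - {id: "?", kind: character, span: 1.2}
        - {id: "!", kind: character, span: 1.2}
        - {id: "'", kind: character, span: 1.2}
        - {id: backspace, kind: backspace, span: 2.0}
      - - {id: ABC, kind: function, span: 2.5}
        - {id: space, kind: spacebar, span: 5.0}
        - {id: return, kind: return, span: 2.5}
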