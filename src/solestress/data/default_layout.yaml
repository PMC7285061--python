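# Default 16-sensor insole layout (right foot).
#
# This is a SYNTHETIC stand-in layout: coordinates are plausible for a
# UK 9-10 insole but were authored for this package, not measured from
# any commercial product. All centre-of-pressure computations accept a
# layout argument so a measured layout substitutes cleanly.
#
# Units: millimetres. Origin: posterior-lateral heel corner.
# x: medio-lateral (0 = lateral edge), y: anterior-posterior (0 = heel).
# Sensors 1-12 are the forefoot array, 13-16 the heel array.
sensors:
  - {id: 1,  x: 15, y: 230, region: forefoot}
  - {id: 2,  x: 38, y: 230, region: forefoot}
  - {id: 3,  x: 61, y: 230, region: forefoot}
  - {id: 4,  x: 84, y: 230, region: forefoot}
  - {id: 5,  x: 15, y: 200, region: forefoot}
  - {id: 6,  x: 38, y: 200, region: forefoot}
  - {id: 7,  x: 61, y: 200, region: forefoot}
  - {id: 8,  x: 84, y: 200, region: forefoot}
  - {id: 9,  x: 15, y: 170, region: forefoot}
  - {id: 10, x: 38, y: 170, region: forefoot}
  - {id: 11, x: 61, y: 170, region: forefoot}
  - {id: 12, x: 84, y: 170, region: forefoot}
  - {id: 13, x: 28, y: 55,  region: rearfoot}
  - {id: 14, x: 62, y: 55,  region: rearfoot}
  - {id: 15, x: 28, y: 25,  region: rearfoot}
  - {id: 16, x: 62, y: 25,  region: rearfoot}
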