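# Cultivar -> leaf-area-density group.  Illustrative, not exhaustive:
# unknown cultivars require an explicit group override.
cultivars:
  low:
    - Satsuma
    - Owari
    - Okitsu
    - Lemon
    - Fino
  medium:
    - Clemenules
    - Marisol
    - Oronules
    - Nadorcott
    - Nova
    - Orri
    - Washington
    - Lane late
  high:
    - Fortune
    - Garbi
    - Moncada
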