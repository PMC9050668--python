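# Breed classifier fixture: a small recognised-breed set with Kennel Club
# breed-group assignments, covering the breeds used in the worked examples.
# "American Bulldog" is deliberately recognised but unmapped, exercising the
# purebred / non-KC-recognised distinction.  Real analyses supply their own
# (much larger) lookup in the same format.
recognised_breeds:
  - American Bulldog
  - Beagle
  - Border Collie
  - Boxer
  - Cavalier King Charles Spaniel
  - Chihuahua
  - Cocker Spaniel
  - English Bulldog
  - French Bulldog
  - German Shepherd Dog
  - Husky
  - Jack Russell Terrier
  - Labrador Retriever
  - Pug
  - Shih-tzu
  - Springer Spaniel
  - Staffordshire Bull Terrier
  - Yorkshire Terrier
breed_groups:
  Beagle: Hound
  Border Collie: Pastoral
  Boxer: Working
  Cavalier King Charles Spaniel: Toy
  Chihuahua: Toy
  Cocker Spaniel: Gundog
  English Bulldog: Utility
  French Bulldog: Utility
  German Shepherd Dog: Pastoral
  Husky: Working
  Jack Russell Terrier: Terrier
  Labrador Retriever: Gundog
  Pug: Toy
  Shih-tzu: Utility
  Springer Spaniel: Gundog
  Staffordshire Bull Terrier: Terrier
  Yorkshire Terrier: Toy
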