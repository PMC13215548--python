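# Default region adjacency fixture: the eight administrative divisions of
# Bangladesh with an approximate first-order neighbourhood relation.
# This file is data, not code — edit it (or point the pipeline at another
# file of the same shape) to change the spatial structure.
regions:
  - Barishal
  - Chattogram
  - Dhaka
  - Khulna
  - Mymensingh
  - Rajshahi
  - Rangpur
  - Sylhet
edges:
  - [Barishal, Khulna]
  - [Barishal, Dhaka]
  - [Barishal, Chattogram]
  - [Chattogram, Dhaka]
  - [Chattogram, Sylhet]
  - [Dhaka, Khulna]
  - [Dhaka, Mymensingh]
  - [Dhaka, Rajshahi]
  - [Dhaka, Sylhet]
  - [Khulna, Rajshahi]
  - [Mymensingh, Sylhet]
  - [Mymensingh, Rangpur]
  - [Rajshahi, Rangpur]
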