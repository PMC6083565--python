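<svg xmlns="http://www.w3.org/2000/svg" width="104" height="133" viewBox="0 0 104 133">
<rect width="104" height="133" fill="white"/>
<line x1="72.0" y1="66.6" x2="52.0" y2="101.3" stroke="red" stroke-width="1.5" stroke-dasharray="3,4"/>
<line x1="72.0" y1="66.6" x2="52.0" y2="32.0" stroke="red" stroke-width="1.5" stroke-dasharray="3,4"/>
<line x1="72.0" y1="66.6" x2="52.0" y2="101.3" stroke="red" stroke-width="1.5" stroke-dasharray="3,4"/>
<line x1="72.0" y1="66.6" x2="52.0" y2="32.0" stroke="red" stroke-width="1.5" stroke-dasharray="3,4"/>
<line x1="72.0" y1="66.6" x2="52.0" y2="101.3" stroke="red" stroke-width="1.5" stroke-dasharray="3,4"/>
<line x1="52.0" y1="101.3" x2="72.0" y2="66.6" stroke="black" stroke-width="2"/>
<line x1="72.0" y1="66.6" x2="52.0" y2="32.0" stroke="black" stroke-width="2"/>
<line x1="52.0" y1="32.0" x2="32.0" y2="66.6" stroke="black" stroke-width="2"/>
<line x1="32.0" y1="66.6" x2="52.0" y2="101.3" stroke="black" stroke-width="2"/>
<line x1="52.0" y1="101.3" x2="72.0" y2="66.6" stroke="black" stroke-width="2"/>
<line x1="72.0" y1="66.6" x2="52.0" y2="32.0" stroke="black" stroke-width="2"/>
<line x1="52.0" y1="32.0" x2="32.0" y2="66.6" stroke="black" stroke-width="2"/>
<line x1="32.0" y1="66.6" x2="52.0" y2="101.3" stroke="black" stroke-width="2"/>
<line x1="52.0" y1="101.3" x2="72.0" y2="66.6" stroke="black" stroke-width="2"/>
<line x1="72.0" y1="66.6" x2="52.0" y2="32.0" stroke="black" stroke-width="2"/>
<line x1="52.0" y1="32.0" x2="32.0" y2="66.6" stroke="black" stroke-width="2"/>
<line x1="32.0" y1="66.6" x2="52.0" y2="101.3" stroke="black" stroke-width="2"/>
<line x1="52.0" y1="101.3" x2="72.0" y2="66.6" stroke="black" stroke-width="2"/>
<circle cx="52.0" cy="101.3" r="8.8" fill="#333333" stroke="black" stroke-width="1.5"/>
<text x="52.0" y="89.3" font-size="10" text-anchor="middle" fill="#666666">1</text>
<circle cx="72.0" cy="66.6" r="8.8" fill="#333333" stroke="black" stroke-width="1.5"/>
<text x="72.0" y="54.6" font-size="10" text-anchor="middle" fill="#666666">2</text>
<circle cx="52.0" cy="32.0" r="8.8" fill="white" stroke="black" stroke-width="1.5"/>
<text x="52.0" y="20.0" font-size="10" text-anchor="middle" fill="#666666">3</text>
<circle cx="32.0" cy="66.6" r="8.8" fill="white" stroke="black" stroke-width="1.5"/>
<text x="32.0" y="54.6" font-size="10" text-anchor="middle" fill="#666666">4</text>
<circle cx="52.0" cy="101.3" r="8.8" fill="#333333" stroke="black" stroke-width="1.5"/>
<text x="52.0" y="89.3" font-size="10" text-anchor="middle" fill="#666666">5</text>
<circle cx="72.0" cy="66.6" r="8.8" fill="white" stroke="black" stroke-width="1.5"/>
<text x="72.0" y="54.6" font-size="10" text-anchor="middle" fill="#666666">6</text>
<circle cx="52.0" cy="32.0" r="8.8" fill="#333333" stroke="black" stroke-width="1.5"/>
<text x="52.0" y="20.0" font-size="10" text-anchor="middle" fill="#666666">7</text>
<circle cx="32.0" cy="66.6" r="8.8" fill="white" stroke="black" stroke-width="1.5"/>
<text x="32.0" y="54.6" font-size="10" text-anchor="middle" fill="#666666">8</text>
<circle cx="52.0" cy="101.3" r="8.8" fill="#333333" stroke="black" stroke-width="1.5"/>
<text x="52.0" y="89.3" font-size="10" text-anchor="middle" fill="#666666">9</text>
<circle cx="72.0" cy="66.6" r="8.8" fill="white" stroke="black" stroke-width="1.5"/>
<text x="72.0" y="54.6" font-size="10" text-anchor="middle" fill="#666666">10</text>
<circle cx="52.0" cy="32.0" r="8.8" fill="#333333" stroke="black" stroke-width="1.5"/>
<text x="52.0" y="20.0" font-size="10" text-anchor="middle" fill="#666666">11</text>
<circle cx="32.0" cy="66.6" r="8.8" fill="white" stroke="black" stroke-width="1.5"/>
<text x="32.0" y="54.6" font-size="10" text-anchor="middle" fill="#666666">12</text>
<circle cx="52.0" cy="101.3" r="8.8" fill="#333333" stroke="black" stroke-width="1.5"/>
<text x="52.0" y="89.3" font-size="10" text-anchor="middle" fill="#666666">13</text>
<circle cx="72.0" cy="66.6" r="8.8" fill="white" stroke="black" stroke-width="1.5"/>
<text x="72.0" y="54.6" font-size="10" text-anchor="middle" fill="#666666">14</text>
</svg>
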